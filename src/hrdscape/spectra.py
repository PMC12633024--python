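"""SBS96 channel definitions and the packaged synthetic spectrum panel.

Channel convention
------------------
The 96 single-base-substitution channels are indexed on the pyrimidine
strand: six substitution types (C>A, C>G, C>T, T>A, T>C, T>G) in that order,
each crossed with the 16 flanking-base combinations in alphabetical order of
the 5' then the 3' base.  Channel labels read ``A[C>A]A`` ... ``T[T>G]T``.
Purine-strand substitutions are reverse-complemented onto this strand before
counting.

The packaged panel is *synthetic*: six COSMIC-shaped but artificial 96-channel
probability vectors emulating a flat background (SBS5-like), a clock-like CpG
process (SBS1-like), the near-flat HRD signature (SBS3-like), a mismatch-
repair process (SBS6-like), a polymerase-epsilon proofreading process
(SBS10-like) and an 8-oxo-guanine sequencing artifact (SBS45-like).  They are
versioned with the package and deterministic; real COSMIC spectra can be
substituted anywhere a panel is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The 96 channel labels in canonical order.
CHANNELS: List[str] = [
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
]
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_of(ref: str, alt: str, context: str) -> int:
    """Map an SNV (ref, alt, reference-strand trinucleotide) to its channel.

    Purine references are reverse-complemented onto the pyrimidine strand.
    Raises ``KeyError`` for non-ACGT bases and ``ValueError`` for inconsistent
    context.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} inconsistent with ref {ref!r}")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = reverse_complement(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return _CHANNEL_INDEX[label]


@dataclass(frozen=True)
class Spectrum96:
    """A named 96-channel substitution probability vector (sums to 1)."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (96,):
            raise ValueError(f"spectrum {self.name!r} must have 96 channels, got {p.shape}")
        if (p < 0).any():
            raise ValueError(f"spectrum {self.name!r} has negative entries")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"spectrum {self.name!r} does not sum to 1 (sum={p.sum()!r})")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_weights(cls, name: str, weights: Sequence[float]) -> "Spectrum96":
        w = np.asarray(weights, dtype=float)
        return cls(name=name, probs=w / w.sum())


def _sub_mask(sub: str) -> np.ndarray:
    mask = np.zeros(96)
    j = SUBSTITUTIONS.index(sub)
    mask[j * 16 : (j + 1) * 16] = 1.0
    return mask


def _context_weight(sub: str, five: Optional[str] = None, three: Optional[str] = None) -> np.ndarray:
    """Indicator over channels of one substitution type with optional flank constraints."""
    w = np.zeros(96)
    j = SUBSTITUTIONS.index(sub)
    for a, b5 in enumerate(BASES):
        for b, b3 in enumerate(BASES):
            if five is not None and b5 != five:
                continue
            if three is not None and b3 != three:
                continue
            w[j * 16 + a * 4 + b] = 1.0
    return w


def default_panel() -> List[Spectrum96]:
    """The packaged six-spectrum panel (see module docstring)."""
    flat = np.ones(96)

    # SBS5-like: broadly flat with a mild T>C transcription-coupled tilt.
    background = 1.0 * flat + 3.0 * _sub_mask("T>C") + 1.0 * _sub_mask("C>T")

    # SBS1-like: C>T at CpG (NCG contexts) dominates.
    clock = 0.15 * flat + 12.0 * _context_weight("C>T", three="G")

    # SBS3-like: near-uniform across all 96 channels with slight C>G/C>T excess.
    sig3 = 1.0 * flat + 0.35 * _sub_mask("C>G") + 0.25 * _sub_mask("C>T")

    # SBS6-like: C>T at non-CpG contexts plus some C>A; low elsewhere.
    mmr = (
        0.1 * flat
        + 6.0 * (_sub_mask("C>T") - _context_weight("C>T", three="G"))
        + 2.0 * _context_weight("C>A", five="G")
    )

    # SBS10-like: sharp C>A at TCT and T>G at TTT peaks.
    pole = (
        0.05 * flat
        + 30.0 * _context_weight("C>A", five="T", three="T")
        + 12.0 * _context_weight("T>G", five="T", three="T")
    )

    # SBS45-like (8-oxo-G artifact): C>A dominated, enriched at NCA/NCT.
    sbs45 = 0.1 * flat + 5.0 * _sub_mask("C>A") + 3.0 * _context_weight("C>A", three="A")

    return [
        Spectrum96.from_weights("background", background),
        Spectrum96.from_weights("clock", clock),
        Spectrum96.from_weights("sig3", sig3),
        Spectrum96.from_weights("mmr", mmr),
        Spectrum96.from_weights("pole", pole),
        Spectrum96.from_weights("sbs45", sbs45),
    ]


def panel_matrix(panel: Sequence[Spectrum96]) -> np.ndarray:
    """Stack a panel into a (96, n_signatures) column matrix."""
    return np.column_stack([s.probs for s in panel])


def mix_spectra(panel: Sequence[Spectrum96], weights: Dict[str, float], name: str) -> Spectrum96:
    """Convex combination of panel spectra by name; weights are renormalized."""
    by_name = {s.name: s for s in panel}
    missing = set(weights) - set(by_name)
    if missing:
        raise KeyError(f"unknown spectra in mixture: {sorted(missing)}")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("mixture weights must have positive sum")
    p = np.zeros(96)
    for key, w in weights.items():
        if w < 0:
            raise ValueError("mixture weights must be non-negative")
        p += (w / total) * by_name[key].probs
    return Spectrum96(name=name, probs=p)
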