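"""Shared fixtures: simulated cohorts at several scales and the full
pipeline recovery run (session-scoped; the heavy ones are built once)."""

from __future__ import annotations

from dataclasses import replace

import pytest

from hrdscape.datatypes import default_genome
from hrdscape.experiments import hrd_recovery_experiment
from hrdscape.simulate import default_config, simulate_cohort
from hrdscape.spectra import default_panel


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def small_config(seed: int = 7, n_per_type: int = 25):
    cfg = default_config(seed)
    return replace(
        cfg, tumor_types=tuple(replace(tt, n_samples=n_per_type) for tt in cfg.tumor_types)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 75-sample cohort for unit tests of readers, catalogs and counters."""
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def recovery():
    """The packaged 600-sample strong-effect cohort run end to end through
    the classifier pipeline (simulation + training; shared across tests)."""
    return hrd_recovery_experiment(seed=1)


@pytest.fixture(scope="session")
def default_cohort(recovery):
    return recovery.cohort
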