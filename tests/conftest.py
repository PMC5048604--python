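"""Shared fixtures: small and full-size synthetic cohorts.

Heavy cohorts are session-scoped; individual tests draw their own test
samples from the shared simulator (the generator is stateful but seeded, so
the suite is deterministic end to end).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adaptnipt.calling import ReferencePanelModel
from adaptnipt.gc_correction import chromosome_profile, loess_correct
from adaptnipt.simulate import CohortSimulator, SimulationConfig


def profile_sample(sim: CohortSimulator, bc, **loess_kw):
    corrected = loess_correct(bc, sim.bins, **loess_kw)
    return chromosome_profile(corrected, sim.bins, bc.sample_id, bc.counts)


@pytest.fixture(scope="session")
def small_sim() -> CohortSimulator:
    """A fast 600-bin genome at 1M reads for unit-level checks."""
    return CohortSimulator(SimulationConfig(n_bins=600, depth=1e6, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full study conditions: 396-sample euploid panel, 5000-bin genome,
    3.3M reads, with the fitted reference model."""
    sim = CohortSimulator(SimulationConfig(n_panel=396, seed=7))
    profiles = [profile_sample(sim, sim.sample(f"R{i:04d}")) for i in range(396)]
    model = ReferencePanelModel.build(profiles)
    return sim, model


@pytest.fixture
def toy_bins() -> pd.DataFrame:
    """Three-chromosome toy bin table with hand-set GC values."""
    rows = []
    for chrom, gcs in [(1, [0.40, 0.42, 0.44]), (2, [0.45, 0.46]), (3, [0.50])]:
        for i, gc in enumerate(gcs):
            rows.append((chrom, i * 20_000, (i + 1) * 20_000, gc, True))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "usable"])


def make_profiles(rf21, gc21, chrom: int = 21, prefix: str = "S"):
    """Single-chromosome profile list for scoring/selection unit tests."""
    from adaptnipt.gc_correction import ChromosomeProfile

    profs = []
    for i, (rf, gc) in enumerate(zip(rf21, gc21)):
        profs.append(
            ChromosomeProfile(
                f"{prefix}{i:03d}",
                np.array([chrom]),
                np.array([float(rf)]),
                np.array([float(rf)]),
                np.array([float(gc)]),
            )
        )
    return profs
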