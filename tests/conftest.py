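"""Shared fixtures: the heavy Monte Carlo runs are done once per session.

All fixtures are seeded; problem sizes are desk-scale (1-2e5 protons), the
package's default working point for the comparison table and depth-dose
anchors.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from protonfocus import pipeline
from protonfocus.pipeline import TABLE1_SCENARIOS
from protonfocus.scoring import DoseMetrics, DoseTally


SEED = 20260924


@pytest.fixture(scope="session")
def table1_runs() -> dict[str, tuple[DoseMetrics, DoseTally]]:
    """Metrics and tallies of the three comparison scenarios at n=2e5."""
    # per-column proton budgets: the collimated column needs 1e6 because
    # only ~6% survive the bore; the conventional focused column needs 6e5
    # to pin its 80-20 penumbra below the comparison tolerance; the
    # shoot-through column's metrics converge at 2e5 (its track length per
    # proton is ~2.5x longer)
    budgets = {"CECP": 1_000_000, "CEFP": 600_000, "HEFP": 200_000}
    runs = {}
    for name, base in TABLE1_SCENARIOS.items():
        params = replace(base, n_protons=budgets[name], seed=SEED)
        metrics, tally, _ = pipeline.scenario_metrics(name, params)
        runs[name] = (metrics, tally)
    return runs


@pytest.fixture(scope="session")
def bragg_150() -> DoseTally:
    """Broad-beam (sigma0=6 mm, parallel) 150 MeV depth-dose run."""
    return pipeline.broad_beam_depth_dose(150.0, n_protons=200_000, seed=SEED)


@pytest.fixture(scope="session")
def bragg_100() -> DoseTally:
    """Broad-beam 100 MeV depth-dose run."""
    return pipeline.broad_beam_depth_dose(100.0, n_protons=200_000, seed=SEED)


@pytest.fixture(scope="session")
def bragg_350() -> DoseTally:
    """Broad-beam 350 MeV depth-dose run in an extended phantom."""
    return pipeline.broad_beam_depth_dose(350.0, n_protons=100_000, seed=SEED)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
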