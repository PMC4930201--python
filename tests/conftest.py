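import numpy as np
import pandas as pd
import pytest

from gpdrivers.gp import GPConfig
from gpdrivers.pipeline import AnalysisConfig, run_analysis
from gpdrivers.preprocess import FeatureTable
from gpdrivers.synthetic import SyntheticSpec

# Reduced-scale GP settings used throughout the suite for speed: the full
# configuration (population 1000, 500 generations, 50 runs/fold) targets
# multi-hour production runs, not tests.
REDUCED_GP = dict(
    population_size=200,
    max_generations=60,
    init_depth=(2, 4),
    max_depth=8,
    stagnation_window=20,
)


def make_table(columns: dict, target, years=None) -> FeatureTable:
    """Small hand-built FeatureTable (values assumed already normalised)."""
    n = len(next(iter(columns.values())))
    if years is None:
        years = list(range(2000, 2000 + n))
    idx = pd.Index(years, name="year")
    data = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()},
                        index=idx)
    tgt = pd.Series(np.asarray(target, dtype=float), index=idx, name="target")
    meta = pd.DataFrame({"name": list(data.columns), "base": list(data.columns),
                         "season": "annual", "category": "physical"})
    return FeatureTable(data=data, target=tgt, target_name="target", meta=meta)


@pytest.fixture(scope="session")
def recovery_results():
    """Ten reduced-scale end-to-end runs of the driver-recovery study.

    Target recipe 0.8*x3 - 0.6*x7 + N(0, 0.1) over 20 AR(1) candidates plus
    two pure-noise negative-control columns; 13 folds x 5 runs, population
    200, 60 generations, keep fraction 0.2.  Shared by the recovery and
    negative-control checks so the expensive runs happen once.
    """
    results = []
    for seed in range(10):
        cfg = AnalysisConfig(
            synthetic=SyntheticSpec(
                n_years=39,
                n_candidates=20,
                n_noise_candidates=2,
                target_recipe="0.8*x3 - 0.6*x7",
                noise_sd=0.1,
                seed=seed,
            ),
            gp=GPConfig(**REDUCED_GP),
            runs_per_fold=5,
            keep_fraction=0.2,
            seed=seed,
        )
        results.append(run_analysis(cfg))
    return results
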