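import warnings

import numpy as np
import pandas as pd
import pytest

from biomepred.cv_engine import make_folds, run_cv
from biomepred.otu_preprocess import OTUTable
from biomepred.predictors import BLHyper, EnsembleParams, RKHSHyper
from biomepred.synthetic_cohort import (
    CohortConfig,
    TraitSpec,
    default_trait_specs,
    generate_cohort,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_table(counts, sample_ids=None, otu_ids=None, timepoint="wk15"):
    """Small OTUTable helper used across test modules."""
    counts = np.asarray(counts)
    n, p = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    otu_ids = otu_ids or [f"otu{j}" for j in range(p)]
    idx = pd.Index(sample_ids, name="sample_id")
    return OTUTable(
        pd.DataFrame(counts, index=idx, columns=otu_ids),
        pd.DataFrame(
            {"animal": [f"a_{s}" for s in sample_ids], "timepoint": timepoint},
            index=idx,
        ),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Mid-sized synthetic trial shared by structural tests."""
    cfg = CohortConfig(
        n_sires=8, n_replicates=3, n_otus=100, depth=2000, seed=7
    )
    specs = [
        TraitSpec("Week14BF", 1.25, 0.28, microbiome_r2=0.4, fixed_r2=0.2),
        TraitSpec("Week14Wt", 68.78, 9.88, microbiome_r2=0.0, fixed_r2=0.2),
    ]
    return generate_cohort(cfg, specs)


@pytest.fixture(scope="session")
def factorial_cv():
    """Full 12-trait x 3-timepoint x 4-algorithm x 2 factorial at miniature scale.

    Sized for structure checks (cell counts, assembly, summaries), not
    for accuracy: the benchmark contract is exercised on every cell.
    """
    cfg = CohortConfig(
        n_sires=4,
        n_replicates=2,
        pigs_per_pen=4,
        sampled_per_pen=2,
        dropout_rate=0.0,
        n_otus=30,
        depth=300,
        seed=42,
    )
    bundle = generate_cohort(cfg, default_trait_specs())
    folds = make_folds(
        bundle.phenotypes.index, bundle.phenotypes["sire"], n_repeats=5, seed=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = run_cv(
            bundle.phenotypes,
            bundle.otu_tables,
            folds,
            bl_hyper=BLHyper(iterations=150, burn_in=50, thin=1, seed=1),
            rkhs_hyper=RKHSHyper(iterations=150, burn_in=50, thin=1, seed=1),
            ens_params=EnsembleParams(n_trees=25, seed=1),
        )
    return bundle, folds, results
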