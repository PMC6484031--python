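"""Sire-stratified cross-validation benchmark.

Implements the evaluation machinery: repeated stratified ~70/30 splits
that keep every sire family equally represented in training and test,
Pearson-correlation accuracy and MSE per repeat, t-based 90% confidence
intervals, a null-vs-microbiome significance flag (CI non-overlap by
default, Welch t-test optionally) and cross-model averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .jsd_kernel import jsd_matrix, kernel_from_jsd
from .otu_preprocess import OTUTable, build_W, to_relative
from .predictors import (
    BLHyper,
    EnsembleParams,
    RKHSHyper,
    build_fixed_design,
    fit_bayesian_lasso,
    fit_forest,
    fit_gbm,
    fit_null,
    fit_rkhs,
    select_lambda,
)

__all__ = [
    "FoldAssignment",
    "make_folds",
    "accuracy_pearson",
    "run_cv",
    "summarize_cv",
    "ALGORITHMS",
]

ALGORITHMS = ("BL", "RKHS", "RF", "GBM")


@dataclass
class FoldAssignment:
    """One stratified train/test split."""

    repeat: int
    train_ids: pd.Index
    test_ids: pd.Index
    per_sire_train_fraction: pd.Series

    def __post_init__(self) -> None:
        if len(set(self.train_ids) & set(self.test_ids)):
            raise ValueError("train and test sets overlap")


def make_folds(
    animals,
    sires,
    n_repeats: int = 5,
    train_frac: float = 0.70,
    seed: int = 0,
) -> list[FoldAssignment]:
    """Repeated sire-stratified random splits.

    Within each sire family, round(train_frac * n) animals go to
    training in every repeat (ties broken by the seeded RNG); a sire
    with a single offspring is assigned to training with a warning.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be strictly between 0 and 1")
    animals = pd.Index(animals)
    sires = pd.Series(np.asarray(sires), index=animals)
    rng = np.random.default_rng(seed)
    groups = {s: idx for s, idx in sires.groupby(sires).groups.items()}
    singles = [s for s, idx in groups.items() if len(idx) == 1]
    if singles:
        warnings.warn(
            f"sire(s) with a single offspring assigned to training: {singles[:5]}",
            stacklevel=2,
        )
    folds = []
    for rep in range(1, n_repeats + 1):
        train, test = [], []
        frac = {}
        for s, idx in groups.items():
            idx = list(idx)
            n_s = len(idx)
            n_train = int(round(train_frac * n_s))
            if n_s == 1:
                n_train = 1
            n_train = min(max(n_train, 1), n_s if n_s == 1 else n_s - 0)
            perm = rng.permutation(n_s)
            train.extend(idx[i] for i in perm[:n_train])
            test.extend(idx[i] for i in perm[n_train:])
            frac[s] = n_train / n_s
        if not test:
            raise ValueError("empty test set; lower train_frac")
        folds.append(
            FoldAssignment(
                repeat=rep,
                train_ids=pd.Index(train),
                test_ids=pd.Index(test),
                per_sire_train_fraction=pd.Series(frac),
            )
        )
    return folds


def accuracy_pearson(pred, obs) -> float:
    """Pearson correlation between predicted and observed phenotypes.

    Returns NaN (with a warning) when the predictions are constant, so a
    degenerate fit is excluded from averages rather than crashing.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("pred and obs length mismatch")
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(obs) == 0:
        raise ValueError("observed values are constant")
    if np.std(pred) == 0:
        warnings.warn("constant predictions; accuracy undefined (NaN)", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(pred, obs).statistic)


def _prep_timepoint(table: OTUTable, kernel_repair: str):
    """Per-timepoint quantities that do not depend on the fold split."""
    comps = to_relative(table)
    M = kernel_from_jsd(jsd_matrix(comps), repair=kernel_repair)
    animal_of = table.metadata["animal"].rename_axis("sample_id")
    sample_of = animal_of.reset_index().set_index("animal")["sample_id"]
    return M, sample_of


def run_cv(
    phenotypes: pd.DataFrame,
    otu_tables: dict,
    folds: list[FoldAssignment],
    traits=None,
    timepoints=None,
    algorithms=ALGORITHMS,
    bl_hyper: BLHyper | None = None,
    rkhs_hyper: RKHSHyper | None = None,
    ens_params: EnsembleParams | None = None,
    bl_lambda_grid=None,
    kernel_repair: str = "clip",
    factors: tuple[str, ...] = ("sex", "replicate", "sire"),
    covariates: tuple[str, ...] = ("weaning_wt",),
) -> pd.DataFrame:
    """Run the full null-vs-microbiome benchmark.

    For every cell of the trait x timepoint x algorithm x {null, biom}
    factorial and every fold repeat: fit on training animals, predict
    the held-out animals, record Pearson accuracy and MSE.  The OTU
    scaling matrix W is recomputed on each training fold (no leakage);
    the JSD kernel is computed once per timepoint from compositions.
    If ``bl_lambda_grid`` has more than one value, lambda is re-selected
    inside each training fold.

    Returns a long DataFrame with one row per cell x repeat.
    """
    bl_hyper = bl_hyper or BLHyper()
    rkhs_hyper = rkhs_hyper or RKHSHyper()
    ens_params = ens_params or EnsembleParams()
    if traits is None:
        traits = [c for c in phenotypes.columns if c not in
                  ("sire", "replicate", "sex", "pen", "weaning_wt")]
    if timepoints is None:
        timepoints = list(otu_tables.keys())
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")

    X_all = build_fixed_design(phenotypes, factors=factors, covariates=covariates)
    prep = {tp: _prep_timepoint(otu_tables[tp], kernel_repair) for tp in timepoints}

    records = []
    for tp in timepoints:
        M, sample_of = prep[tp]
        table = otu_tables[tp]
        avail = phenotypes.index.intersection(sample_of.index)
        for fold in folds:
            train = fold.train_ids.intersection(avail)
            test = fold.test_ids.intersection(avail)
            if len(test) < 3 or len(train) < 10:
                warnings.warn(
                    f"fold {fold.repeat} at {tp}: too few animals, cell skipped",
                    stacklevel=2,
                )
                continue
            tr_samples = sample_of.loc[train]
            te_samples = sample_of.loc[test]
            sm = build_W(table, reference=tr_samples)
            W_tr = sm.W.loc[tr_samples].set_axis(train, axis=0)
            W_te = sm.W.loc[te_samples].set_axis(test, axis=0)
            X_tr, X_te = X_all.loc[train], X_all.loc[test]
            M_animal = M.M.set_axis(table.metadata["animal"], axis=0).set_axis(
                table.metadata["animal"], axis=1
            )

            for trait in traits:
                y_tr = phenotypes.loc[train, trait].to_numpy(dtype=float)
                y_te = phenotypes.loc[test, trait].to_numpy(dtype=float)
                for alg in algorithms:
                    for biom in (False, True):
                        try:
                            pred = _fit_cell(
                                alg, biom, y_tr, X_tr, X_te, W_tr, W_te,
                                M_animal, train, test,
                                bl_hyper, rkhs_hyper, ens_params,
                                bl_lambda_grid, fold.repeat,
                            )
                        except Exception as exc:  # failed cell is missing, not fatal
                            warnings.warn(
                                f"cell ({trait},{tp},{alg},biom={biom},"
                                f"rep={fold.repeat}) failed: {exc}",
                                stacklevel=2,
                            )
                            continue
                        records.append(
                            {
                                "trait": trait,
                                "timepoint": tp,
                                "algorithm": alg,
                                "biom": biom,
                                "repeat": fold.repeat,
                                "accuracy": accuracy_pearson(pred, y_te),
                                "mse": float(np.mean((pred - y_te) ** 2)),
                            }
                        )
    return pd.DataFrame.from_records(records)


def _fit_cell(
    alg, biom, y_tr, X_tr, X_te, W_tr, W_te, M_animal, train, test,
    bl_hyper, rkhs_hyper, ens_params, bl_lambda_grid, repeat,
):
    """Fit one algorithm/biom cell on a training fold and predict the test fold."""
    if alg == "BL":
        if not biom:
            return fit_null(y_tr, X_tr).predict(X_te)
        hyper = bl_hyper
        if bl_lambda_grid is not None and len(list(bl_lambda_grid)) > 1:
            lam = select_lambda(
                y_tr, X_tr, W_tr, grid=bl_lambda_grid,
                hyper=bl_hyper, seed=bl_hyper.seed + repeat,
            )
            hyper = replace(bl_hyper, lam=lam)
        fit = fit_bayesian_lasso(y_tr, X_tr, W_tr, hyper)
        return fit.predict(X_te, W_te)
    if alg == "RKHS":
        if not biom:
            return fit_null(y_tr, X_tr).predict(X_te)
        fit = fit_rkhs(
            y_tr, pd.concat([X_tr, X_te]), M_animal, rkhs_hyper,
            train_ids=train, test_ids=test,
        )
        return fit.predictions.loc[test].to_numpy()
    # tree ensembles: one-hot design features, plus W columns for biom
    feats_tr = pd.concat([X_tr.drop(columns="intercept"), W_tr], axis=1) if biom \
        else X_tr.drop(columns="intercept")
    feats_te = pd.concat([X_te.drop(columns="intercept"), W_te], axis=1) if biom \
        else X_te.drop(columns="intercept")
    if alg == "RF":
        return fit_forest(y_tr, feats_tr, ens_params).predict(feats_te)
    if alg == "GBM":
        return fit_gbm(y_tr, feats_tr, ens_params).predict(feats_te)
    raise ValueError(f"unknown algorithm {alg!r}")


def summarize_cv(
    results: pd.DataFrame,
    ci_level: float = 0.90,
    sig_method: str = "ci_overlap",
    model_average: bool = True,
) -> pd.DataFrame:
    """Per-cell means, SDs, t-based CIs and null-vs-biom significance flags.

    The significance flag marks a biom cell whose 90% CI does not
    overlap the CI of the matching null cell (``sig_method="welch"``
    uses a Welch t-test at alpha = 1 - ci_level instead).  With
    ``model_average=True``, extra rows with algorithm="AVG" hold the
    across-algorithm mean accuracy per trait/timepoint/biom (performance
    averaging, not prediction averaging).
    """
    if sig_method not in ("ci_overlap", "welch"):
        raise ValueError(f"unknown sig_method {sig_method!r}")
    keys = ["trait", "timepoint", "algorithm", "biom"]
    rows = []
    for vals, grp in results.groupby(keys, sort=False):
        acc = grp["accuracy"].dropna().to_numpy()
        n = len(acc)
        if n < 2:
            warnings.warn(f"cell {vals}: fewer than 2 repeats, CI undefined",
                          stacklevel=2)
        mean = float(np.mean(acc)) if n else float("nan")
        sd = float(np.std(acc, ddof=1)) if n >= 2 else float("nan")
        half = (
            stats.t.ppf(0.5 + ci_level / 2, df=n - 1) * sd / np.sqrt(n)
            if n >= 2
            else float("nan")
        )
        rows.append(
            dict(
                zip(keys, vals),
                n_repeats=n,
                accuracy_mean=mean,
                accuracy_sd=sd,
                ci_lo=mean - half,
                ci_hi=mean + half,
                mse_mean=float(grp["mse"].mean()),
                mse_sd=float(grp["mse"].std(ddof=1)) if n >= 2 else float("nan"),
            )
        )
    summary = pd.DataFrame(rows)

    # null-vs-biom significance per (trait, timepoint, algorithm)
    summary["significant_vs_null"] = False
    idx = summary.set_index(["trait", "timepoint", "algorithm", "biom"]).index
    for i, row in summary.iterrows():
        if not row["biom"]:
            continue
        key = (row["trait"], row["timepoint"], row["algorithm"], False)
        if key not in idx:
            continue
        null_row = summary.loc[idx == key].iloc[0]
        if sig_method == "ci_overlap":
            sig = (row["ci_lo"] > null_row["ci_hi"]) or (row["ci_hi"] < null_row["ci_lo"])
        else:
            a = results.query(
                "trait == @row.trait and timepoint == @row.timepoint "
                "and algorithm == @row.algorithm and biom"
            )["accuracy"].dropna()
            b = results.query(
                "trait == @row.trait and timepoint == @row.timepoint "
                "and algorithm == @row.algorithm and not biom"
            )["accuracy"].dropna()
            sig = stats.ttest_ind(a, b, equal_var=False).pvalue < (1 - ci_level)
        summary.loc[i, "significant_vs_null"] = bool(sig)

    if model_average:
        avg_rows = []
        for (trait, tp, biom), grp in summary.groupby(["trait", "timepoint", "biom"]):
            avg_rows.append(
                {
                    "trait": trait,
                    "timepoint": tp,
                    "algorithm": "AVG",
                    "biom": biom,
                    "n_repeats": int(grp["n_repeats"].max()),
                    "accuracy_mean": float(grp["accuracy_mean"].mean()),
                    "accuracy_sd": float(grp["accuracy_mean"].std(ddof=1))
                    if len(grp) >= 2 else float("nan"),
                    "ci_lo": float("nan"),
                    "ci_hi": float("nan"),
                    "mse_mean": float(grp["mse_mean"].mean()),
                    "mse_sd": float("nan"),
                    "significant_vs_null": False,
                }
            )
        summary = pd.concat([summary, pd.DataFrame(avg_rows)], ignore_index=True)
    return summary
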