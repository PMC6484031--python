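"""Pipeline orchestration, configuration, file I/O and reporting.

Ties the stages together: simulate (or load) -> preprocess -> kernels ->
cross-validation -> post-analysis, writing CSV/TSV reports and a
provenance manifest.  Every stage draws its seed from the master seed
via a named-substream scheme, so toggling one stage never shifts the
randomness of another.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cv_engine import ALGORITHMS, make_folds, run_cv, summarize_cv
from .otu_preprocess import OTUTable, filter_otus, goods_coverage, rarefy
from .post_analysis import assemble_table, fit_post_lmm, ls_means, type3_anova
from .predictors import BLHyper, EnsembleParams, RKHSHyper, classify_timepoint
from .synthetic_cohort import CohortConfig, TraitSpec, default_trait_specs, generate_cohort

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline", "read_tables"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed by name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated configuration of an end-to-end run."""

    seed: int = 0
    out_dir: str = "biomepred_out"
    # synthetic cohort (used when no input paths are given)
    cohort: dict = field(default_factory=dict)
    microbiome_r2: float = 0.25
    fixed_r2: float = 0.15
    causal_timepoint: str = "wk15"
    # external data paths (all three required together)
    otu_paths: dict | None = None  # timepoint -> counts TSV
    metadata_path: str | None = None
    phenotype_path: str | None = None
    # preprocessing
    min_total: int = 1200
    depth: int = 10000
    # scope
    traits: list | None = None
    timepoints: list | None = None
    algorithms: tuple = ALGORITHMS
    # cross-validation
    n_repeats: int = 5
    train_frac: float = 0.70
    # model settings
    bl: dict = field(default_factory=dict)
    rkhs: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    bl_lambda_grid: list | None = None
    kernel_repair: str = "clip"
    classify: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        paths = (self.otu_paths, self.metadata_path, self.phenotype_path)
        if any(p is not None for p in paths) and not all(p is not None for p in paths):
            raise ValueError(
                "otu_paths, metadata_path and phenotype_path must be given together"
            )
        for p in ("metadata_path", "phenotype_path"):
            v = getattr(self, p)
            if v is not None and not Path(v).exists():
                raise FileNotFoundError(f"config field {p}: no such file {v!r}")
        if self.otu_paths:
            for tp, v in self.otu_paths.items():
                if not Path(v).exists():
                    raise FileNotFoundError(f"otu_paths[{tp!r}]: no such file {v!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_tables(
    otu_paths: dict, metadata_path, phenotype_path
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Load OTU tables per timepoint plus the phenotype/design table.

    Verifies sample-to-animal joins and reports unmatched samples;
    raises on duplicate ids, non-integer counts or unknown timepoints.
    Returns (tables, phenotypes, exclusion report).
    """
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    pheno = pd.read_csv(phenotype_path, index_col="animal")
    if not pheno.index.is_unique:
        raise ValueError("duplicate animal ids in phenotype table")
    unknown_tp = set(meta["timepoint"]) - set(otu_paths)
    if unknown_tp:
        raise ValueError(f"metadata has unknown timepoint label(s): {sorted(unknown_tp)}")
    tables = {}
    excluded = []
    for tp, path in otu_paths.items():
        counts = pd.read_csv(path, sep="\t", index_col="sample_id")
        for col, dt in counts.dtypes.items():
            if not np.issubdtype(dt, np.integer):
                raise TypeError(f"{path}: non-integer counts in column {col!r}")
        meta_tp = meta[meta["timepoint"] == tp]
        missing_meta = counts.index.difference(meta_tp.index)
        if len(missing_meta):
            raise ValueError(f"{path}: samples missing metadata: {list(missing_meta)[:5]}")
        table = OTUTable(counts, meta_tp.loc[counts.index])
        no_pheno = table.metadata.index[~table.metadata["animal"].isin(pheno.index)]
        for s in no_pheno:
            excluded.append({"sample_id": s, "timepoint": tp, "reason": "no phenotype"})
        keep = table.sample_ids.difference(no_pheno)
        tables[tp] = table.subset_samples(keep)
    report = pd.DataFrame(excluded, columns=["sample_id", "timepoint", "reason"])
    return tables, pheno, report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full benchmark and write the report bundle.

    Writes: cohort files (synthetic runs), Good's coverage summary, the
    per-repeat accuracy table, accuracy/MSE summaries, the timepoint
    confusion matrix, the Type III ANOVA table, LS-means per term, and a
    provenance manifest.  Returns the in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "stage_seeds": {},
    }

    def stage(name):
        s = stage_seed(config.seed, name)
        manifest["stage_seeds"][name] = s
        return s

    results: dict = {}
    t0 = time.time()

    # --- simulate or load ---------------------------------------------------
    if config.otu_paths:
        tables, pheno, excl = read_tables(
            config.otu_paths, config.metadata_path, config.phenotype_path
        )
        excl.to_csv(out / "excluded_samples.csv", index=False)
        truth = None
    else:
        cohort_cfg = CohortConfig(**{**config.cohort, "seed": stage("simulate")})
        specs = [
            TraitSpec(s.name, s.mean, s.sd, config.microbiome_r2, config.fixed_r2)
            for s in default_trait_specs()
            if config.traits is None or s.name in config.traits
        ]
        bundle = generate_cohort(
            cohort_cfg, specs, causal_timepoint=config.causal_timepoint, out_dir=out / "cohort"
        )
        tables, pheno, truth = bundle.otu_tables, bundle.phenotypes, bundle.truth
        results["bundle"] = bundle
    timings["simulate_or_load"] = time.time() - t0

    # --- preprocess ---------------------------------------------------------
    t0 = time.time()
    seed_pre = stage("preprocess")
    processed = {}
    coverage = {}
    for i, (tp, table) in enumerate(tables.items()):
        filtered = filter_otus(table, min_total=config.min_total)
        processed[tp] = rarefy(filtered, depth=config.depth, seed=seed_pre + i)
        coverage[tp] = goods_coverage(processed[tp])
    pd.DataFrame(
        {tp: {"mean": c.mean(), "sd": c.std(ddof=1)} for tp, c in coverage.items()}
    ).T.to_csv(out / "goods_coverage.csv", index_label="timepoint")
    results["tables"] = processed
    timings["preprocess"] = time.time() - t0

    # --- timepoint classifier (confusion matrix) ----------------------------
    if config.classify:
        t0 = time.time()
        ens = EnsembleParams(**{**config.ensemble, "seed": stage("classify")})
        cm = classify_timepoint(processed, n_folds=5, params=ens, seed=stage("classify"))
        cm.matrix.to_csv(out / "confusion_matrix.csv", index_label="true_timepoint")
        results["confusion"] = cm
        timings["classify"] = time.time() - t0

    # --- cross-validation ----------------------------------------------------
    t0 = time.time()
    design_cols = {"sire", "replicate", "sex", "pen", "weaning_wt"}
    traits = config.traits or [c for c in pheno.columns if c not in design_cols]
    folds = make_folds(
        pheno.index, pheno["sire"], n_repeats=config.n_repeats,
        train_frac=config.train_frac, seed=stage("folds"),
    )
    cv = run_cv(
        pheno,
        processed,
        folds,
        traits=traits,
        timepoints=config.timepoints,
        algorithms=config.algorithms,
        bl_hyper=BLHyper(**{**config.bl, "seed": stage("bl")}),
        rkhs_hyper=RKHSHyper(**{**config.rkhs, "seed": stage("rkhs")}),
        ens_params=EnsembleParams(**{**config.ensemble, "seed": stage("ensemble")}),
        bl_lambda_grid=config.bl_lambda_grid,
        kernel_repair=config.kernel_repair,
    )
    cv.to_csv(out / "accuracy_cv.csv", index=False)
    summary = summarize_cv(cv)
    summary.to_csv(out / "accuracy_summary.csv", index=False)
    _mse_table(summary).to_csv(out / "mse_table.csv", index=False)
    results["cv"] = cv
    results["summary"] = summary
    timings["cv"] = time.time() - t0

    # --- post-analysis --------------------------------------------------------
    t0 = time.time()
    records = assemble_table(cv)
    records.to_csv(out / "accuracy_records.csv", index=False)
    if records[["Timepoint", "Algorithm", "Trait"]].nunique().prod() >= 4:
        fit = fit_post_lmm(records)
        anova = type3_anova(fit)
        anova.to_csv(out / "anova_type3.csv")
        lsm = {}
        for term in list(fit.terms):
            lsm[term] = ls_means(fit, term)
            lsm[term].to_csv(out / f"ls_means_{term.replace(':', '_')}.csv", index=False)
        results["post"] = {"fit": fit, "anova": anova, "ls_means": lsm}
    timings["post"] = time.time() - t0

    manifest["timings_sec"] = {k: round(v, 3) for k, v in timings.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results


def _mse_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide MSE report: one row per method/trait, columns per timepoint."""
    sub = summary[summary["algorithm"] != "AVG"].copy()
    sub["method"] = np.where(sub["biom"], sub["algorithm"], "Null")
    rows = []
    for (trait, method), grp in sub.groupby(["trait", "method"], sort=False):
        row = {"Method": method, "Trait": trait}
        for _, r in grp.iterrows():
            row[f"MSE ({r['timepoint']})"] = r["mse_mean"]
            row[f"SD ({r['timepoint']})"] = r["mse_sd"]
        rows.append(row)
    return pd.DataFrame(rows)
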