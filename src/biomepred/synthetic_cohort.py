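"""Synthetic swine cohort generator with known ground truth.

Emulates a commercial grow-finish trial: offspring of purebred Duroc
sires penned as single-sex paternal half-sib groups, with fecal 16S OTU
profiles collected at weaning, week 15 and week 22 of the trial and a
panel of growth/carcass traits recorded per animal.  The generator's
defaults follow the trial dimensions (28 sires x 6 replicates x 2 pens
of 20 with 4 animals sampled per pen = 1344 sampled animals, ~1039 with
all three timepoints, 1755 OTUs rarefied to 10,000 reads) and the
published trait means/SDs, and it exposes the ground-truth effect
structure so that downstream estimators can be tested for recovery.

Community model: each timepoint has a baseline composition; per-sample
compositions are Dirichlet draws around that baseline and counts are
multinomial at the configured depth (a Dirichlet-multinomial, giving
overdispersed compositional counts).  Six designated "dominant" OTU
blocks carry ~96% of the expected mass, mirroring the six phyla that
dominate real swine fecal communities.

Trait model: y = mu + X b + W o + e, where X carries sex, replicate,
sire and the weaning-weight covariate, W is the centered/scaled OTU
count matrix of the causal timepoint (week 15 by default) and o is a
vector of OTU effects.  Each component is rescaled so the realized
variance shares match the requested ``fixed_r2`` / ``microbiome_r2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .otu_preprocess import OTUTable, build_W

__all__ = [
    "CohortConfig",
    "TraitSpec",
    "GroundTruth",
    "CohortBundle",
    "TABLE3_TRAITS",
    "default_trait_specs",
    "generate_design",
    "generate_microbiome",
    "generate_phenotypes",
    "generate_cohort",
]

#: Published summary (mean, SD) of the 12 growth and carcass traits.
TABLE3_TRAITS: dict[str, tuple[float, float]] = {
    "ADGBto14": (0.57, 0.08),
    "ADGWto14": (0.64, 0.10),
    "ADG14to22": (0.86, 0.16),
    "ADG14toMKT": (0.89, 0.14),
    "Week14Wt": (68.78, 9.88),
    "Week14BF": (1.25, 0.28),
    "Week14LD": (4.24, 0.48),
    "Week14LEA": (28.38, 4.57),
    "Week22Wt": (117.26, 13.37),
    "Week22BF": (2.00, 0.53),
    "Week22LD": (5.59, 0.52),
    "Week22LEA": (43.90, 5.69),
}

TIMEPOINTS = ("wean", "wk15", "wk22")

#: Expected mass of the six dominant OTU blocks and its split among them,
#: calibrated to the ~96% of reads falling in six phyla, with the first
#: block (the Firmicutes analogue) holding the majority.
_DOMINANT_MASS = 0.965
_BLOCK_WEIGHTS = np.array([0.52, 0.27, 0.09, 0.05, 0.025, 0.01])


@dataclass(frozen=True)
class CohortConfig:
    """Dimensions and sampling parameters of a synthetic trial."""

    n_sires: int = 28
    n_replicates: int = 6
    pens_per_sire_per_replicate: int = 2  # one pen per sex
    pigs_per_pen: int = 20
    sampled_per_pen: int = 4
    dropout_rate: float = 1.0 - 1039.0 / 1344.0  # calibrated to ~1039 complete
    n_otus: int = 1755
    depth: int = 10000
    timepoints: tuple[str, ...] = TIMEPOINTS
    concentration: float = 50.0  # Dirichlet overdispersion (smaller = noisier)
    separation: float = 0.8  # log-scale divergence of timepoint baselines
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_sires",
            "n_replicates",
            "pens_per_sire_per_replicate",
            "pigs_per_pen",
            "sampled_per_pen",
            "n_otus",
            "depth",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.timepoints) != 3:
            raise ValueError("exactly 3 timepoints are required")
        if self.sampled_per_pen > self.pigs_per_pen:
            raise ValueError("cannot sample more pigs than the pen holds")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")

    @property
    def n_animals(self) -> int:
        return (
            self.n_sires
            * self.n_replicates
            * self.pens_per_sire_per_replicate
            * self.sampled_per_pen
        )


@dataclass(frozen=True)
class TraitSpec:
    """Target moments and variance partition of one simulated trait.

    ``microbiome_r2`` is the share of trait variance carried by the OTU
    effects W o; ``fixed_r2`` the share carried by sex + replicate +
    sire + weaning weight.  ``n_causal_otus = 0`` means dense effects
    (every OTU contributes).
    """

    name: str
    mean: float
    sd: float
    microbiome_r2: float = 0.25
    fixed_r2: float = 0.15
    n_causal_otus: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("trait sd must be > 0")
        if self.microbiome_r2 < 0 or self.fixed_r2 < 0:
            raise ValueError("variance shares must be non-negative")
        if self.microbiome_r2 + self.fixed_r2 > 1.0:
            raise ValueError("microbiome_r2 + fixed_r2 must be <= 1")
        if self.n_causal_otus < 0:
            raise ValueError("n_causal_otus must be >= 0")


def default_trait_specs(
    microbiome_r2: float = 0.25, fixed_r2: float = 0.15, n_causal_otus: int = 0
) -> list[TraitSpec]:
    """The 12-trait panel with published means/SDs and a common variance split."""
    return [
        TraitSpec(name, mean, sd, microbiome_r2, fixed_r2, n_causal_otus)
        for name, (mean, sd) in TABLE3_TRAITS.items()
    ]


@dataclass
class GroundTruth:
    """Simulated effect structure, kept for recovery tests."""

    fixed_effects: dict[str, pd.Series]  # per trait: named coefficient vector
    otu_effects: dict[str, np.ndarray]  # per trait: length n_otus (scaled)
    microbiome_signal: dict[str, pd.Series]  # per trait: realized W o per animal
    fixed_signal: dict[str, pd.Series]
    residual_variance: dict[str, float]
    baselines: dict[str, np.ndarray] = field(default_factory=dict)
    concentration: float = float("nan")
    causal_timepoint: str = "wk15"


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(8)[stream])


def generate_design(config: CohortConfig) -> pd.DataFrame:
    """Sampled-animal herd design: sire x replicate x sex fully crossed.

    Returns one row per sampled animal with columns animal, sire,
    replicate, sex, pen and weaning_wt (kg).  Pens are single-sex,
    single-sire; only the ``sampled_per_pen`` animals chosen for
    carcass measurement and swabbing appear.
    """
    rng = _rng_for(config.seed, 0)
    sexes = ["F", "C"][: config.pens_per_sire_per_replicate]
    # small paternal contribution to weaning weight, one value per sire
    sire_wean = rng.normal(0.0, 0.3, size=config.n_sires)
    rows = []
    k = 0
    for rep in range(1, config.n_replicates + 1):
        for sire in range(1, config.n_sires + 1):
            for pen_i in range(config.pens_per_sire_per_replicate):
                sex = sexes[pen_i % len(sexes)]
                pen = f"r{rep}_s{sire}_{sex}{pen_i // len(sexes) or ''}"
                for _ in range(config.sampled_per_pen):
                    k += 1
                    rows.append(
                        {
                            "animal": f"pig{k:05d}",
                            "sire": sire,
                            "replicate": rep,
                            "sex": sex,
                            "pen": pen,
                            "weaning_wt": 5.5
                            + sire_wean[sire - 1]
                            + rng.normal(0.0, 0.9),
                        }
                    )
    design = pd.DataFrame(rows).set_index("animal")
    return design


def _block_sizes(n_otus: int) -> list[int]:
    """OTU counts of the six dominant blocks (~55% of OTUs) plus the tail."""
    frac = np.array([0.22, 0.13, 0.08, 0.05, 0.04, 0.03])
    sizes = np.maximum((frac * n_otus).astype(int), 1)
    return sizes.tolist()


def timepoint_baselines(config: CohortConfig) -> dict[str, np.ndarray]:
    """Expected composition per timepoint.

    A shared base composition assigns ``_DOMINANT_MASS`` to six OTU
    blocks (log-normal weights within block); each timepoint then
    perturbs the base on the log scale with standard deviation
    ``separation`` and renormalizes, so separation=0 yields identical
    baselines.
    """
    rng = _rng_for(config.seed, 1)
    p = config.n_otus
    sizes = _block_sizes(p)
    base = np.empty(p)
    start = 0
    for size, mass in zip(sizes, _BLOCK_WEIGHTS * _DOMINANT_MASS):
        w = rng.lognormal(0.0, 1.0, size=size)
        base[start : start + size] = mass * w / w.sum()
        start += size
    tail = rng.lognormal(0.0, 1.0, size=p - start)
    base[start:] = (1.0 - _DOMINANT_MASS) * tail / tail.sum()
    baselines = {}
    for tp in config.timepoints:
        z = rng.normal(0.0, 1.0, size=p)
        q = base * np.exp(config.separation * z)
        baselines[tp] = q / q.sum()
    return baselines


def dominant_block_mass(config: CohortConfig) -> pd.Series:
    """Expected mass of the six dominant blocks per timepoint baseline."""
    cut = sum(_block_sizes(config.n_otus))
    baselines = timepoint_baselines(config)
    return pd.Series({tp: q[:cut].sum() for tp, q in baselines.items()})


def generate_microbiome(
    design: pd.DataFrame,
    config: CohortConfig,
    separation: float | None = None,
) -> dict[str, OTUTable]:
    """Dirichlet-multinomial OTU tables, one per timepoint.

    Every sample's counts sum exactly to ``config.depth``.  Sample ids
    are ``{animal}@{timepoint}``.
    """
    if separation is not None:
        config = replace(config, separation=separation)
    if config.depth < 1:
        raise ValueError("depth must be >= 1")
    baselines = timepoint_baselines(config)
    rng = _rng_for(config.seed, 2)
    otu_ids = [f"OTU{j + 1:04d}" for j in range(config.n_otus)]
    animals = design.index
    tables: dict[str, OTUTable] = {}
    for tp in config.timepoints:
        alpha = config.concentration * baselines[tp]
        probs = rng.dirichlet(alpha, size=len(animals))
        counts = np.empty((len(animals), config.n_otus), dtype=np.int64)
        for i in range(len(animals)):
            counts[i] = rng.multinomial(config.depth, probs[i])
        sample_ids = pd.Index([f"{a}@{tp}" for a in animals], name="sample_id")
        meta = pd.DataFrame(
            {"animal": list(animals), "timepoint": tp}, index=sample_ids
        )
        tables[tp] = OTUTable(
            pd.DataFrame(counts, index=sample_ids, columns=otu_ids), meta
        )
    return tables


def generate_phenotypes(
    design: pd.DataFrame,
    otus: OTUTable,
    specs: list[TraitSpec],
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate traits as y = mu + X b + W o + e on the causal OTU layer.

    The microbiome signal W o is orthogonalized against the fixed-effect
    design before rescaling, so the realized variance partition matches
    the requested shares exactly up to residual sampling noise.
    """
    rng = np.random.default_rng(seed)
    sample_by_animal = (
        otus.metadata.rename_axis("sample_id").reset_index().set_index("animal")["sample_id"]
    )
    missing = design.index.difference(sample_by_animal.index)
    if len(missing):
        raise ValueError(
            f"causal OTU table missing {len(missing)} animal(s), e.g. {list(missing)[:3]}"
        )
    sm = build_W(otus)
    W = sm.W.loc[sample_by_animal.loc[design.index]].to_numpy()
    n, p = W.shape

    # fixed-effect design: one-hot sex/replicate/sire + centered weaning weight
    X_parts = [
        pd.get_dummies(design["sex"], prefix="sex").astype(float),
        pd.get_dummies(design["replicate"], prefix="rep").astype(float),
        pd.get_dummies(design["sire"], prefix="sire").astype(float),
    ]
    ww = design["weaning_wt"] - design["weaning_wt"].mean()
    X_full = pd.concat(X_parts + [ww.rename("weaning_wt")], axis=1)
    Q, _ = np.linalg.qr(
        np.column_stack([np.ones(n), X_full.to_numpy()])
    )  # basis for orthogonalization

    pheno = design.copy()
    truth = GroundTruth(
        fixed_effects={},
        otu_effects={},
        microbiome_signal={},
        fixed_signal={},
        residual_variance={},
        causal_timepoint=str(otus.metadata["timepoint"].iloc[0]),
    )
    for spec in specs:
        b = pd.Series(rng.normal(0.0, 1.0, size=X_full.shape[1]), index=X_full.columns)
        # give the weaning-weight covariate a positive slope so early-gain
        # traits correlate with weaning weight through the shared covariate
        b["weaning_wt"] = abs(b["weaning_wt"])
        f = X_full.to_numpy() @ b.to_numpy()
        f = f - f.mean()
        f_sd = f.std()
        if spec.fixed_r2 > 0 and f_sd > 0:
            f = f * (spec.sd * np.sqrt(spec.fixed_r2) / f_sd)
            b = b * (spec.sd * np.sqrt(spec.fixed_r2) / f_sd)
        else:
            f = np.zeros(n)
            b = b * 0.0

        o = rng.normal(0.0, 1.0, size=p)
        if spec.n_causal_otus and spec.n_causal_otus < p:
            idx = rng.choice(p, size=spec.n_causal_otus, replace=False)
            mask = np.zeros(p, dtype=bool)
            mask[idx] = True
            o[~mask] = 0.0
        g = W @ o
        g = g - Q @ (Q.T @ g)  # orthogonal to fixed design incl. intercept
        g_sd = g.std()
        if spec.microbiome_r2 > 0 and g_sd > 0:
            scale = spec.sd * np.sqrt(spec.microbiome_r2) / g_sd
            g = g * scale
            o = o * scale
        else:
            g = np.zeros(n)
            o = o * 0.0

        resid_var = spec.sd**2 * max(1.0 - spec.microbiome_r2 - spec.fixed_r2, 0.0)
        e = rng.normal(0.0, np.sqrt(resid_var), size=n) if resid_var > 0 else np.zeros(n)
        pheno[spec.name] = spec.mean + f + g + e

        truth.fixed_effects[spec.name] = b
        truth.otu_effects[spec.name] = o
        truth.microbiome_signal[spec.name] = pd.Series(g, index=design.index)
        truth.fixed_signal[spec.name] = pd.Series(f, index=design.index)
        truth.residual_variance[spec.name] = resid_var
    return pheno, truth


@dataclass
class CohortBundle:
    """One generated trial: design, OTU tables, phenotypes and the truth."""

    config: CohortConfig
    design: pd.DataFrame
    otu_tables: dict[str, OTUTable]  # post-dropout, what a study would observe
    phenotypes: pd.DataFrame
    truth: GroundTruth
    missing: pd.DataFrame  # animal x timepoint boolean mask of dropped swabs

    @property
    def complete_animals(self) -> pd.Index:
        return self.missing.index[~self.missing.any(axis=1)]

    def write(self, out_dir) -> dict[str, str]:
        """Write OTU TSVs, metadata TSV and phenotype CSV; returns paths."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        metas = []
        for tp, table in self.otu_tables.items():
            cpath = out / f"otu_{tp}.tsv"
            counts = table.counts.copy()
            counts.index.name = "sample_id"
            counts.to_csv(cpath, sep="\t")
            paths[f"otu_{tp}"] = str(cpath)
            metas.append(table.metadata)
        mpath = out / "samples.tsv"
        meta = pd.concat(metas)
        meta.index.name = "sample_id"
        meta.to_csv(mpath, sep="\t")
        paths["samples"] = str(mpath)
        ppath = out / "phenotypes.csv"
        self.phenotypes.to_csv(ppath, index_label="animal")
        paths["phenotypes"] = str(ppath)
        return paths


def generate_cohort(
    config: CohortConfig,
    specs: list[TraitSpec] | None = None,
    causal_timepoint: str = "wk15",
    out_dir=None,
) -> CohortBundle:
    """Full synthetic trial under a single seed.

    The microbiome is generated for every animal at every timepoint;
    phenotypes are driven by the complete causal-timepoint layer; swab
    dropout is then applied to the emitted OTU tables, each dropped-out
    animal losing one uniformly chosen timepoint.
    """
    if specs is None:
        specs = default_trait_specs()
    if causal_timepoint not in config.timepoints:
        raise ValueError(f"unknown causal timepoint {causal_timepoint!r}")
    design = generate_design(config)
    tables_full = generate_microbiome(design, config)
    pheno, truth = generate_phenotypes(
        design, tables_full[causal_timepoint], specs, seed=int(_rng_for(config.seed, 3).integers(2**31))
    )
    truth.baselines = timepoint_baselines(config)
    truth.concentration = config.concentration
    truth.causal_timepoint = causal_timepoint

    rng = _rng_for(config.seed, 4)
    dropped = rng.random(len(design)) < config.dropout_rate
    which = rng.integers(0, len(config.timepoints), size=len(design))
    missing = pd.DataFrame(
        False, index=design.index, columns=list(config.timepoints)
    )
    for i, animal in enumerate(design.index):
        if dropped[i]:
            missing.iloc[i, which[i]] = True

    observed = {}
    for k, tp in enumerate(config.timepoints):
        keep_animals = design.index[~missing[tp].to_numpy()]
        keep_samples = pd.Index([f"{a}@{tp}" for a in keep_animals])
        observed[tp] = tables_full[tp].subset_samples(keep_samples)

    bundle = CohortBundle(
        config=config,
        design=design,
        otu_tables=observed,
        phenotypes=pheno,
        truth=truth,
        missing=missing,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
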