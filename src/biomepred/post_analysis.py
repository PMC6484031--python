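"""Mixed-model post-analysis of the cross-validation accuracy table.

The benchmark produces one accuracy per repeat of every Timepoint (3) x
Algorithm (4) x Trait (12) x Biom (2) cell.  The post-analysis fits

    y = T + A + Tr + B + T:A + T:Tr + T:B + A:Tr + A:B + Tr:B
        + g(T,A,Tr,B) + e,

with all four main effects and the six pairwise interactions fixed
(sum-to-zero contrasts) and the four-way cell effect g random,
g ~ N(0, sigma2_g), e ~ N(0, sigma2_e).  Because the random effect is a
grouped intercept, REML reduces to a one-dimensional profiled problem
solved exactly here (closed-form per-group inverse).  Type III F tests
use Satterthwaite denominator degrees of freedom combined over
eigencontrasts, and LS-means are marginal means over the balanced
factor grid with SEs from the fitted fixed-effect covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FACTORS",
    "assemble_table",
    "LMMFit",
    "fit_post_lmm",
    "type3_anova",
    "ls_means",
]

FACTORS = ("Timepoint", "Algorithm", "Trait", "Biom")


def assemble_table(cv_results: pd.DataFrame) -> pd.DataFrame:
    """Pool CV results into the accuracy table of the factorial design.

    One row per repeat x trait x timepoint x algorithm x biom with the
    columns Timepoint, Algorithm, Trait, Biom, replicate, accuracy.
    Rows with missing (NaN) accuracy are dropped with a log message.
    """
    df = cv_results.rename(
        columns={
            "timepoint": "Timepoint",
            "algorithm": "Algorithm",
            "trait": "Trait",
            "biom": "Biom",
            "repeat": "replicate",
        }
    )[["Timepoint", "Algorithm", "Trait", "Biom", "replicate", "accuracy"]].copy()
    df["Biom"] = np.where(df["Biom"].astype(bool), "biom", "null")
    n_bad = int(df["accuracy"].isna().sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} record(s) with undefined accuracy",
                      stacklevel=2)
        df = df.dropna(subset=["accuracy"])
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sum-to-zero design construction
# ---------------------------------------------------------------------------

def _sum_code(values: pd.Series, name: str) -> pd.DataFrame:
    """Sum-to-zero (effects) coding: k levels -> k-1 columns.

    Column i is +1 for level i, -1 for the last level, 0 otherwise;
    levels are sorted lexicographically for reproducibility.
    """
    levels = sorted(map(str, pd.unique(values.astype(str))))
    cols = {}
    v = values.astype(str)
    for lev in levels[:-1]:
        col = np.where(v == lev, 1.0, 0.0)
        col = np.where(v == levels[-1], -1.0, col)
        cols[f"{name}[{lev}]"] = col
    return pd.DataFrame(cols, index=values.index)


def _build_design(records: pd.DataFrame):
    """Fixed design with main effects + all pairwise interactions.

    Returns (X matrix, term -> column slice dict, factor level dict).
    """
    mains = {f: _sum_code(records[f], f) for f in FACTORS}
    levels = {f: sorted(map(str, pd.unique(records[f].astype(str)))) for f in FACTORS}
    blocks = [pd.DataFrame({"(Intercept)": np.ones(len(records))},
                           index=records.index)]
    terms = {}
    pos = 1
    for f in FACTORS:
        blocks.append(mains[f])
        terms[f] = slice(pos, pos + mains[f].shape[1])
        pos += mains[f].shape[1]
    for i, f1 in enumerate(FACTORS):
        for f2 in FACTORS[i + 1:]:
            inter = {}
            for c1 in mains[f1].columns:
                for c2 in mains[f2].columns:
                    inter[f"{c1}:{c2}"] = mains[f1][c1] * mains[f2][c2]
            block = pd.DataFrame(inter, index=records.index)
            blocks.append(block)
            terms[f"{f1}:{f2}"] = slice(pos, pos + block.shape[1])
            pos += block.shape[1]
    X = pd.concat(blocks, axis=1)
    return X, terms, levels


# ---------------------------------------------------------------------------
# REML for the grouped-random-intercept model
# ---------------------------------------------------------------------------

def _group_structure(records: pd.DataFrame) -> np.ndarray:
    cell = (
        records[list(FACTORS)].astype(str).agg(":".join, axis=1)
    )
    codes, _ = pd.factorize(cell)
    return codes


def _reml_quantities(X, y, codes, rho):
    """GLS pieces for V0 = I + rho * ZZ' with grouped Z.

    Per group of size m: V0^-1 = I - (rho / (1 + m rho)) J.
    Returns beta, XtViX, r'V0^-1 r, sum log det, n, p.
    """
    n, p = X.shape
    n_groups = codes.max() + 1
    m = np.bincount(codes)
    w = rho / (1.0 + m * rho)  # per-group shrink factor

    def vinv(A):  # V0^-1 @ A for 2-d A
        sums = np.zeros((n_groups, A.shape[1]))
        np.add.at(sums, codes, A)
        return A - (w[codes])[:, None] * sums[codes]

    ViX = vinv(X)
    Viy = vinv(y[:, None])[:, 0]
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    r = y - X @ beta
    quad = float(r @ vinv(r[:, None])[:, 0])
    logdet_v = float(np.sum(np.log1p(m * rho)))
    return beta, XtViX, quad, logdet_v, n, p


def _reml_loglik(X, y, codes, rho):
    beta, XtViX, quad, logdet_v, n, p = _reml_quantities(X, y, codes, rho)
    sigma2 = quad / (n - p)
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * np.log(sigma2) + logdet_v + logdet_x + (n - p)
    )


@dataclass
class LMMFit:
    """REML fit of the accuracy LMM."""

    beta: np.ndarray
    cov_beta: np.ndarray  # sigma2_e * (X' V0^-1 X)^-1
    sigma2_g: float
    sigma2_e: float
    reml_loglik: float
    terms: dict = field(repr=False)
    levels: dict = field(repr=False)
    columns: list = field(repr=False)
    records: pd.DataFrame = field(repr=False)
    codes: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    theta_cov: np.ndarray = field(repr=False)  # asymptotic cov of (sigma2_g, sigma2_e)
    converged: bool = True

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.beta


def fit_post_lmm(records: pd.DataFrame, fix_sigma2_g: float | None = None) -> LMMFit:
    """REML fit of the factorial accuracy model.

    Parameters
    ----------
    records
        Output of :func:`assemble_table` (>= 2 replicates per cell for a
        proper fit).
    fix_sigma2_g
        Freeze the cell variance component (0 reduces the model to OLS,
        used by equivalence checks).
    """
    X_df, terms, levels = _build_design(records)
    X = X_df.to_numpy(dtype=float)
    y = records["accuracy"].to_numpy(dtype=float)
    codes = _group_structure(records)
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough records to fit the factorial model")

    if fix_sigma2_g is not None:
        # rho fixed at fix_sigma2_g / sigma2_e; only exact for the 0 case,
        # which is the one the equivalence oracles need
        if fix_sigma2_g != 0:
            raise ValueError("only fix_sigma2_g=0 is supported")
        rho_hat = 0.0
    else:
        # profile REML over rho = sigma2_g / sigma2_e on a log grid + refine
        def neg(log_rho):
            return -_reml_loglik(X, y, codes, np.exp(log_rho))

        grid = np.linspace(np.log(1e-8), np.log(1e4), 40)
        vals = [neg(g) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            neg, bracket=None, bounds=(g0 - 3.0, g0 + 3.0), method="bounded",
            options={"xatol": 1e-10},
        )
        rho_hat = float(np.exp(res.x))
        # boundary: compare against rho = 0
        if -res.fun < _reml_loglik(X, y, codes, 0.0) or rho_hat < 1e-7:
            rho_hat = 0.0

    beta, XtViX, quad, logdet_v, n, p = _reml_quantities(X, y, codes, rho_hat)
    sigma2_e = quad / (n - p)
    sigma2_g = rho_hat * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(XtViX)
    ll = _reml_loglik(X, y, codes, rho_hat)

    # asymptotic covariance of (sigma2_g, sigma2_e) from the numerical
    # Hessian of the REML log-likelihood in that parametrization
    def ll_theta(theta):
        s2g, s2e = theta
        if s2e <= 0 or s2g < 0:
            return -np.inf
        r = s2g / s2e
        b2, XtViX2, quad2, logdet_v2, _, _ = _reml_quantities(X, y, codes, r)
        sign, logdet_x2 = np.linalg.slogdet(XtViX2)
        return -0.5 * (
            (n - p) * np.log(s2e) + logdet_v2 + logdet_x2 + quad2 / s2e
        )

    theta = np.array([max(sigma2_g, 1e-12), sigma2_e])
    h = np.maximum(1e-5 * theta, 1e-12)
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            H[i, j] = (
                ll_theta(theta + ei + ej)
                - ll_theta(theta + ei - ej)
                - ll_theta(theta - ei + ej)
                + ll_theta(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        theta_cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        theta_cov = np.full((2, 2), np.nan)
    if not np.all(np.isfinite(theta_cov)):
        theta_cov = np.diag([2 * sigma2_e**2 / max(n - p, 1)] * 2)

    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        reml_loglik=float(ll),
        terms=terms,
        levels=levels,
        columns=list(X_df.columns),
        records=records,
        codes=codes,
        X=X,
        theta_cov=theta_cov,
    )


def _cov_beta_at(fit: LMMFit, theta) -> np.ndarray:
    s2g, s2e = theta
    rho = max(s2g, 0.0) / s2e
    _, XtViX, _, _, _, _ = _reml_quantities(
        fit.X, fit.records["accuracy"].to_numpy(float), fit.codes, rho
    )
    return s2e * np.linalg.inv(XtViX)


def _satterthwaite_df(fit: LMMFit, ell: np.ndarray) -> float:
    """Satterthwaite df for the scalar contrast ell' beta."""
    theta = np.array([fit.sigma2_g, fit.sigma2_e])
    f0 = float(ell @ fit.cov_beta @ ell)
    grad = np.zeros(2)
    h = np.maximum(1e-4 * np.maximum(theta, 1e-10), 1e-12)
    for i in range(2):
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += h[i]
        tm[i] = max(tm[i] - h[i], 0.0 if i == 0 else 1e-12)
        fp = float(ell @ _cov_beta_at(fit, tp) @ ell)
        fm = float(ell @ _cov_beta_at(fit, tm) @ ell)
        grad[i] = (fp - fm) / (tp[i] - tm[i])
    denom = float(grad @ fit.theta_cov @ grad)
    if denom <= 0:
        return float(len(fit.records) - len(fit.beta))
    return 2.0 * f0**2 / denom


def type3_anova(fit: LMMFit) -> pd.DataFrame:
    """Type III (marginal) F tests for the ten fixed terms.

    With sum-to-zero contrasts the marginal test of a term is the joint
    test that its coefficients vanish.  Denominator degrees of freedom
    follow Satterthwaite's approximation, combined over the
    eigencontrasts of each multi-df term (the lmerTest construction).
    """
    rows = []
    for term, sl in fit.terms.items():
        idx = np.arange(sl.start, sl.stop)
        q = len(idx)
        L = np.zeros((q, len(fit.beta)))
        L[np.arange(q), idx] = 1.0
        Lb = L @ fit.beta
        LCL = L @ fit.cov_beta @ L.T
        F = float(Lb @ np.linalg.solve(LCL, Lb)) / q

        # per-eigencontrast Satterthwaite df, combined
        w, P = np.linalg.eigh(LCL)
        keep = w > w.max() * 1e-12
        dfs = []
        for vec in (P[:, keep]).T:
            ell = L.T @ vec
            dfs.append(_satterthwaite_df(fit, ell))
        dfs = np.asarray(dfs)
        if q == 1:
            df_den = float(dfs[0])
        else:
            good = dfs > 2.0
            if good.sum() == 0:
                df_den = float(len(fit.records) - len(fit.beta))
            else:
                E = float(np.sum(dfs[good] / (dfs[good] - 2.0)))
                df_den = 2.0 * E / (E - good.sum()) if E > good.sum() else float("inf")

        p_val = float(stats.f.sf(F, q, df_den)) if np.isfinite(df_den) else float("nan")
        # lmerTest-style sums of squares on the residual-variance scale
        ss = F * q * fit.sigma2_e
        rows.append(
            {
                "term": term,
                "sum_sq": ss,
                "mean_sq": ss / q,
                "num_df": q,
                "den_df": df_den,
                "F": F,
                "p_value": p_val,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def _grid_design(fit: LMMFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design rows of the full balanced factor grid."""
    from itertools import product

    combos = list(product(*(fit.levels[f] for f in FACTORS)))
    grid = pd.DataFrame(combos, columns=list(FACTORS))
    Xg, _, _ = _build_design(grid.assign(accuracy=0.0))
    return grid, Xg


def ls_means(fit: LMMFit, term: str) -> pd.DataFrame:
    """Least-squares (marginal) means of a main effect or pairwise interaction.

    Averages model predictions over the balanced grid of the remaining
    factors; SEs come from the fitted fixed-effect covariance.
    """
    parts = term.split(":")
    for f in parts:
        if f not in FACTORS:
            raise KeyError(f"unknown term {term!r}")
    grid, Xg = _grid_design(fit)
    Xg = Xg[fit.columns].to_numpy(dtype=float)
    rows = []
    for lev, sub in grid.groupby(parts, sort=True):
        lev = (lev,) if not isinstance(lev, tuple) else lev
        ell = Xg[sub.index.to_numpy()].mean(axis=0)
        est = float(ell @ fit.beta)
        se = float(np.sqrt(ell @ fit.cov_beta @ ell))
        rows.append({**dict(zip(parts, lev)), "estimate": est, "se": se})
    return pd.DataFrame(rows)
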