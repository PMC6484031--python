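"""The four regression families and the timepoint classifier.

Every trait x timepoint cell is fitted twice: a *null* model with only
the design fixed effects (sex, replicate, sire, weaning-weight
covariate) and a *biom* model that adds the OTU information.  The four
families are:

* **null / flat Bayesian linear model** — posterior mean equals least
  squares; used as the null for the two samplers.
* **Bayesian Lasso** — Gibbs sampler for y = mu + X b + W o + e with a
  double-exponential prior on the OTU effects represented as a scale
  mixture of normals: o_j | tau_j^2, sigma_e^2 ~ N(0, tau_j^2 sigma_e^2),
  tau_j^2 ~ Exp(rate lambda^2 / 2), sigma_e^2 ~ scaled-inv-chi^2(df, S),
  b flat.  lambda is fixed and may be chosen by grid search.
* **RKHS kernel regression** — y = mu + X b + u + e with
  u ~ N(0, M sigma_u^2), M the 1 - JSD microbiome similarity kernel;
  Gibbs sampling in the eigenbasis of the training kernel, held-out
  animals predicted by the conditional (kriging) mean.
* **Tree ensembles** — random forest and gradient boosting on the same
  features (one-hot design, optionally + W), via scikit-learn.

Prior scales follow S = Var(y) * R2 * (df + 2) for the random effect and
S_e = Var(y) * (1 - R2_e) * (df_e + 2) for the residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.ensemble import (
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "build_fixed_design",
    "LinearFit",
    "fit_null",
    "BLHyper",
    "BLPosterior",
    "fit_bayesian_lasso",
    "select_lambda",
    "RKHSHyper",
    "RKHSFit",
    "fit_rkhs",
    "EnsembleParams",
    "EnsembleFit",
    "fit_forest",
    "fit_gbm",
    "ConfusionMatrix",
    "classify_timepoint",
]


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------

def build_fixed_design(
    design: pd.DataFrame,
    factors: tuple[str, ...] = ("sex", "replicate", "sire"),
    covariates: tuple[str, ...] = ("weaning_wt",),
    drop_first: bool = True,
) -> pd.DataFrame:
    """Incidence matrix for the design factors plus covariates.

    Includes an intercept column; factor levels are reference-coded
    (first level dropped) so the matrix is full column rank on a
    complete design.
    """
    parts = [pd.Series(1.0, index=design.index, name="intercept")]
    for f in factors:
        d = pd.get_dummies(design[f], prefix=f, drop_first=drop_first).astype(float)
        parts.append(d)
    for c in covariates:
        parts.append(design[c].astype(float))
    return pd.concat(parts, axis=1)


def _drop_aliased(X: np.ndarray, columns) -> tuple[np.ndarray, list]:
    """Remove linearly dependent columns (QR with column pivoting)."""
    if X.shape[1] == 0:
        return X, list(columns)
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = [columns[i] for i in piv[rank:]]
        warnings.warn(
            f"rank-deficient fixed design: dropped aliased column(s) {dropped}",
            stacklevel=3,
        )
        return X[:, keep], [columns[i] for i in keep]
    return X, list(columns)


# ---------------------------------------------------------------------------
# null (flat-prior Bayesian linear == least squares)
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Least-squares fit; the posterior mean of a flat-prior linear model."""

    coef: pd.Series
    sigma2: float
    columns: list

    def predict(self, X_new: pd.DataFrame) -> np.ndarray:
        return X_new[self.columns].to_numpy(dtype=float) @ self.coef.to_numpy()


def fit_null(y, X: pd.DataFrame) -> LinearFit:
    """Fit the fixed-effects-only model by least squares.

    Aliased columns are dropped with a warning; predictions for new rows
    use their design factors only.
    """
    y = np.asarray(y, dtype=float)
    Xm, cols = _drop_aliased(X.to_numpy(dtype=float), list(X.columns))
    beta, _, _, _ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    dof = max(len(y) - Xm.shape[1], 1)
    return LinearFit(
        coef=pd.Series(beta, index=cols),
        sigma2=float(resid @ resid / dof),
        columns=cols,
    )


# ---------------------------------------------------------------------------
# Bayesian Lasso
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BLHyper:
    """Bayesian Lasso hyperparameters.

    ``lam`` is the fixed double-exponential rate-related hyperparameter
    (tau_j^2 ~ Exp(rate lam^2 / 2)); the residual prior is a scaled
    inverse chi-square with ``df_e`` degrees of freedom and scale
    S_e = Var(y) * (1 - R2_e) * (df_e + 2).
    """

    lam: float = 25.0
    df_e: float = 5.0
    R2_e: float = 0.60
    iterations: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.df_e <= 0:
            raise ValueError("df_e must be > 0")
        if not 0 < self.R2_e < 1:
            raise ValueError("R2_e must be in (0, 1)")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")

    def residual_scale(self, var_y: float) -> float:
        return var_y * (1.0 - self.R2_e) * (self.df_e + 2.0)


@dataclass
class BLPosterior:
    """Posterior summaries of the Bayesian Lasso fit."""

    b_mean: pd.Series
    o_mean: pd.Series
    o_sd: pd.Series
    sigma2_mean: float
    b_sd: pd.Series
    n_kept: int
    hyper: BLHyper

    def predict(self, X_new: pd.DataFrame, W_new: pd.DataFrame) -> np.ndarray:
        return (
            X_new[self.b_mean.index].to_numpy(dtype=float) @ self.b_mean.to_numpy()
            + W_new[self.o_mean.index].to_numpy(dtype=float) @ self.o_mean.to_numpy()
        )


def fit_bayesian_lasso(
    y,
    X: pd.DataFrame,
    W: pd.DataFrame,
    hyper: BLHyper,
    fixed_sigma2: float | None = None,
    fixed_tau2: np.ndarray | float | None = None,
) -> BLPosterior:
    """Gibbs sampler for the Bayesian Lasso microbiome model.

    ``fixed_sigma2`` / ``fixed_tau2`` freeze the corresponding updates
    (used by conjugate closed-form cross-checks).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n = len(y)
    Xm, xcols = _drop_aliased(X.to_numpy(dtype=float), list(X.columns))
    Wm = W.to_numpy(dtype=float)
    p = Wm.shape[1]
    rng = np.random.default_rng(hyper.seed)

    var_y = float(np.var(y, ddof=1))
    S_e = hyper.residual_scale(var_y)
    lam2 = hyper.lam**2

    XtX = Xm.T @ Xm
    cF = linalg.cho_factor(XtX + 1e-10 * np.eye(Xm.shape[1]))
    L_x = np.linalg.cholesky(
        linalg.cho_solve(cF, np.eye(Xm.shape[1]))
    )  # for sampling b
    wtw = np.einsum("ij,ij->j", Wm, Wm)
    wtw = np.where(wtw > 0, wtw, 1e-12)

    b = linalg.cho_solve(cF, Xm.T @ y)
    o = np.zeros(p)
    if fixed_tau2 is not None:
        tau2 = np.broadcast_to(np.asarray(fixed_tau2, dtype=float), (p,)).copy()
    else:
        tau2 = np.full(p, 2.0 / lam2)
    sigma2 = fixed_sigma2 if fixed_sigma2 is not None else var_y * (1 - hyper.R2_e)

    r = y - Xm @ b  # o starts at zero
    kept = 0
    b_sum = np.zeros_like(b)
    b_sq = np.zeros_like(b)
    o_sum = np.zeros(p)
    o_sq = np.zeros(p)
    s2_sum = 0.0

    for it in range(hyper.iterations):
        # b | rest  (flat prior): N(lstsq solution on y - Wo, sigma2 (X'X)^-1)
        r_b = r + Xm @ b
        b_hat = linalg.cho_solve(cF, Xm.T @ r_b)
        b = b_hat + np.sqrt(sigma2) * (L_x @ rng.standard_normal(len(b)))
        r = r_b - Xm @ b

        # o_j | rest, coordinate-wise with residual updates
        z = rng.standard_normal(p)
        for j in range(p):
            wj = Wm[:, j]
            oj_old = o[j]
            rj = r + wj * oj_old if oj_old != 0.0 else r
            prec = wtw[j] + 1.0 / tau2[j]
            mean = (wj @ rj) / prec
            oj = mean + np.sqrt(sigma2 / prec) * z[j]
            o[j] = oj
            r = rj - wj * oj

        if not (np.isfinite(sigma2) and np.all(np.isfinite(o))):
            raise FloatingPointError(
                f"Bayesian Lasso sampler diverged at iteration {it}: "
                f"sigma2={sigma2!r}, non-finite OTU effects"
            )

        # tau_j^2 | rest: 1/tau_j^2 ~ InvGaussian(sqrt(lam^2 sigma2 / o_j^2), lam^2)
        if fixed_tau2 is None:
            o2 = np.maximum(o**2, 1e-12)
            mu_ig = np.sqrt(lam2 * sigma2 / o2)
            inv_tau2 = rng.wald(mu_ig, lam2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)

        # sigma_e^2 | rest: scaled-inv-chi2 posterior
        if fixed_sigma2 is None:
            sse = r @ r + np.sum(o**2 / tau2) + S_e
            dfr = n + p + hyper.df_e
            sigma2 = sse / rng.chisquare(dfr)

        if it >= hyper.burn_in and (it - hyper.burn_in) % hyper.thin == 0:
            kept += 1
            b_sum += b
            b_sq += b**2
            o_sum += o
            o_sq += o**2
            s2_sum += sigma2

    b_mean = b_sum / kept
    o_mean = o_sum / kept
    b_var = np.maximum(b_sq / kept - b_mean**2, 0.0)
    o_var = np.maximum(o_sq / kept - o_mean**2, 0.0)
    return BLPosterior(
        b_mean=pd.Series(b_mean, index=xcols),
        o_mean=pd.Series(o_mean, index=W.columns),
        o_sd=pd.Series(np.sqrt(o_var), index=W.columns),
        sigma2_mean=float(s2_sum / kept),
        b_sd=pd.Series(np.sqrt(b_var), index=xcols),
        n_kept=kept,
        hyper=hyper,
    )


def select_lambda(
    y,
    X: pd.DataFrame,
    W: pd.DataFrame,
    grid=(1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0),
    n_folds: int = 5,
    hyper: BLHyper | None = None,
    seed: int = 0,
) -> float:
    """Grid search for the Bayesian Lasso lambda by internal cross-validation.

    Splits the provided (training) data into ``n_folds`` folds, fits the
    sampler at each grid value and returns the value minimizing mean
    validation MSE; ties break toward the smaller lambda.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("lambda grid is empty")
    if len(grid) == 1:
        return grid[0]
    if hyper is None:
        hyper = BLHyper()
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, n_folds)
    mse = np.zeros(len(grid))
    for k, fold in enumerate(folds):
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        Xtr, Xte = X.iloc[mask], X.iloc[~mask]
        Wtr, Wte = W.iloc[mask], W.iloc[~mask]
        for gi, lam in enumerate(grid):
            h = replace(hyper, lam=lam, seed=hyper.seed + 1000 * k + gi)
            fit = fit_bayesian_lasso(y[mask], Xtr, Wtr, h)
            pred = fit.predict(Xte, Wte)
            mse[gi] += np.mean((y[~mask] - pred) ** 2) / n_folds
    best = int(np.argmin(mse + 1e-12 * np.arange(len(grid))))  # ties -> smaller
    return grid[best]


# ---------------------------------------------------------------------------
# RKHS kernel regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RKHSHyper:
    """RKHS sampler hyperparameters.

    Prior scales: S_u = Var(y) * R2_u * (df_u + 2) for the kernel
    variance, S_e = Var(y) * (1 - R2_e) * (df_e + 2) for the residual.
    """

    df_u: float = 5.0
    R2_u: float = 0.30
    df_e: float = 5.0
    R2_e: float = 0.60
    iterations: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.df_u <= 0 or self.df_e <= 0:
            raise ValueError("prior degrees of freedom must be > 0")
        if not 0 < self.R2_u < 1 or not 0 < self.R2_e < 1:
            raise ValueError("R2 values must be in (0, 1)")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")


@dataclass
class RKHSFit:
    """Posterior summaries and held-out predictions of the RKHS model."""

    b_mean: pd.Series
    u_train: pd.Series
    sigma2_u_mean: float
    sigma2_e_mean: float
    sigma2_u_samples: np.ndarray = field(repr=False)
    sigma2_e_samples: np.ndarray = field(repr=False)
    predictions: pd.Series | None = None
    n_kept: int = 0


_EIG_FLOOR = 1e-8


def fit_rkhs(
    y,
    X: pd.DataFrame,
    M,
    hyper: RKHSHyper,
    train_ids=None,
    test_ids=None,
    fixed_sigma2_u: float | None = None,
    fixed_sigma2_e: float | None = None,
) -> RKHSFit:
    """Gibbs sampler for y = mu + X b + u + e with u ~ N(0, M sigma_u^2).

    ``M`` is a KernelMatrix (or DataFrame) over train and test animals;
    the sampler uses only the training submatrix, working in its
    eigenbasis so each sweep is O(n^2).  Held-out animals are predicted
    by the conditional mean M[test,train] M[train,train]^-1 u_train
    added to their fixed-effect predictions.
    """
    Mdf = M.M if hasattr(M, "M") else M
    if train_ids is None:
        train_ids = list(Mdf.index)
    train_ids = pd.Index(train_ids)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(train_ids):
        raise ValueError("y length must match train_ids")
    X_train = X.loc[train_ids]
    Xm, xcols = _drop_aliased(X_train.to_numpy(dtype=float), list(X_train.columns))
    rng = np.random.default_rng(hyper.seed)

    var_y = float(np.var(y, ddof=1))
    S_u = var_y * hyper.R2_u * (hyper.df_u + 2.0)
    S_e = var_y * (1.0 - hyper.R2_e) * (hyper.df_e + 2.0)

    K = Mdf.loc[train_ids, train_ids].to_numpy(dtype=float)
    vals, U = np.linalg.eigh(0.5 * (K + K.T))
    if vals[0] < -1e-6:
        warnings.warn(
            f"training kernel has negative eigenvalue {vals[0]:.3g}; flooring",
            stacklevel=2,
        )
    pos = vals > _EIG_FLOOR
    vals_pos = vals[pos]
    U_pos = U[:, pos]
    k = int(pos.sum())

    XtX = Xm.T @ Xm
    cF = linalg.cho_factor(XtX + 1e-10 * np.eye(Xm.shape[1]))
    L_x = np.linalg.cholesky(linalg.cho_solve(cF, np.eye(Xm.shape[1])))

    b = linalg.cho_solve(cF, Xm.T @ y)
    alpha = np.zeros(k)  # u = U_pos @ alpha
    sigma2_u = fixed_sigma2_u if fixed_sigma2_u is not None else var_y * hyper.R2_u
    sigma2_e = fixed_sigma2_e if fixed_sigma2_e is not None else var_y * (1 - hyper.R2_e)

    kept = 0
    b_sum = np.zeros_like(b)
    u_sum = np.zeros(n)
    s2u_kept = []
    s2e_kept = []

    for it in range(hyper.iterations):
        u = U_pos @ alpha
        # b | rest (flat prior)
        b_hat = linalg.cho_solve(cF, Xm.T @ (y - u))
        b = b_hat + np.sqrt(sigma2_e) * (L_x @ rng.standard_normal(len(b)))

        # alpha | rest: independent normals in the eigenbasis
        resid_proj = U_pos.T @ (y - Xm @ b)
        post_var = 1.0 / (1.0 / sigma2_e + 1.0 / (vals_pos * sigma2_u))
        post_mean = post_var * resid_proj / sigma2_e
        alpha = post_mean + np.sqrt(post_var) * rng.standard_normal(k)
        u = U_pos @ alpha

        # variance components: scaled-inv-chi2 posteriors
        if fixed_sigma2_u is None:
            sigma2_u = (S_u + np.sum(alpha**2 / vals_pos)) / rng.chisquare(
                hyper.df_u + k
            )
        if fixed_sigma2_e is None:
            r = y - Xm @ b - u
            sigma2_e = (S_e + r @ r) / rng.chisquare(hyper.df_e + n)

        if not (np.isfinite(sigma2_u) and np.isfinite(sigma2_e)):
            raise FloatingPointError(f"RKHS sampler diverged at iteration {it}")

        if it >= hyper.burn_in and (it - hyper.burn_in) % hyper.thin == 0:
            kept += 1
            b_sum += b
            u_sum += u
            s2u_kept.append(sigma2_u)
            s2e_kept.append(sigma2_e)

    b_mean = b_sum / kept
    u_mean = u_sum / kept

    predictions = None
    if test_ids is not None and len(test_ids):
        test_ids = pd.Index(test_ids)
        K_inv_u = U_pos @ ((U_pos.T @ u_mean) / vals_pos)
        u_test = Mdf.loc[test_ids, train_ids].to_numpy(dtype=float) @ K_inv_u
        X_test = X.loc[test_ids, xcols].to_numpy(dtype=float)
        predictions = pd.Series(X_test @ b_mean + u_test, index=test_ids)

    return RKHSFit(
        b_mean=pd.Series(b_mean, index=xcols),
        u_train=pd.Series(u_mean, index=train_ids),
        sigma2_u_mean=float(np.mean(s2u_kept)),
        sigma2_e_mean=float(np.mean(s2e_kept)),
        sigma2_u_samples=np.asarray(s2u_kept),
        sigma2_e_samples=np.asarray(s2e_kept),
        predictions=predictions,
        n_kept=kept,
    )


# ---------------------------------------------------------------------------
# tree ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleParams:
    """Shared settings of the random forest and gradient boosting fits.

    Defaults follow the benchmark configuration: 1500 trees, floor(sqrt(p))
    features per split, MSE split criterion and unrestricted depth for the
    forest; depth 3, shrinkage 0.01, squared-error loss and 0.5 bagging
    fraction per iteration for the boosting machine.
    """

    n_trees: int = 1500
    gbm_depth: int = 3
    gbm_shrinkage: float = 0.01
    gbm_bag_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.gbm_depth < 1:
            raise ValueError("gbm_depth must be >= 1")
        if self.gbm_shrinkage < 0:
            raise ValueError("gbm_shrinkage must be >= 0")
        if not 0 < self.gbm_bag_fraction <= 1:
            raise ValueError("gbm_bag_fraction must be in (0, 1]")


@dataclass
class EnsembleFit:
    """Fitted tree ensemble with a uniform predict surface."""

    model: object
    columns: list
    train_mean: float
    kind: str  # "rf" or "gbm"

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if self.model is None:
            return np.full(len(features), self.train_mean)
        return self.model.predict(features[self.columns].to_numpy(dtype=float))

    def staged_train_loss(self, features: pd.DataFrame, y) -> np.ndarray:
        """Mean squared training loss after each boosting iteration."""
        if self.kind != "gbm" or self.model is None:
            raise ValueError("staged loss is defined for fitted GBM models only")
        y = np.asarray(y, dtype=float)
        Xm = features[self.columns].to_numpy(dtype=float)
        return np.array(
            [np.mean((y - p) ** 2) for p in self.model.staged_predict(Xm)]
        )


def fit_forest(y, features: pd.DataFrame, params: EnsembleParams) -> EnsembleFit:
    """Bagged regression forest: floor(sqrt(p)) features per split, full depth."""
    if features.shape[1] == 0:
        raise ValueError("forest requires at least one feature")
    y = np.asarray(y, dtype=float)
    if params.n_trees == 0:
        return EnsembleFit(None, list(features.columns), float(y.mean()), "rf")
    model = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features="sqrt",
        criterion="squared_error",
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(features.to_numpy(dtype=float), y)
    return EnsembleFit(model, list(features.columns), float(y.mean()), "rf")


def fit_gbm(y, features: pd.DataFrame, params: EnsembleParams) -> EnsembleFit:
    """Gradient-boosted trees with squared-error loss and per-iteration bagging."""
    if features.shape[1] == 0:
        raise ValueError("boosting requires at least one feature")
    y = np.asarray(y, dtype=float)
    if params.n_trees == 0 or params.gbm_shrinkage == 0:
        # an empty committee (or zero shrinkage) predicts the training mean
        return EnsembleFit(None, list(features.columns), float(y.mean()), "gbm")
    model = GradientBoostingRegressor(
        n_estimators=params.n_trees,
        max_depth=params.gbm_depth,
        learning_rate=params.gbm_shrinkage,
        loss="squared_error",
        subsample=params.gbm_bag_fraction,
        random_state=params.seed,
    )
    model.fit(features.to_numpy(dtype=float), y)
    return EnsembleFit(model, list(features.columns), float(y.mean()), "gbm")


# ---------------------------------------------------------------------------
# timepoint classifier
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Row-normalized confusion matrix averaged over folds."""

    matrix: pd.DataFrame  # rows = true timepoint, columns = predicted
    per_class_accuracy: pd.Series
    overall_accuracy: float


def classify_timepoint(
    tables: dict,
    n_folds: int = 5,
    params: EnsembleParams | None = None,
    seed: int = 0,
) -> ConfusionMatrix:
    """Random-forest classification of samples into their sampling time.

    Stacks the per-timepoint OTU tables, runs a stratified K-fold
    cross-validation with a random-forest classifier (same ensemble
    defaults, classification splitting) and returns the row-normalized
    confusion matrix averaged over folds.
    """
    if params is None:
        params = EnsembleParams()
    labels = list(tables.keys())
    counts = pd.concat([t.counts for t in tables.values()], axis=0)
    y = np.concatenate(
        [np.full(t.n_samples, i) for i, t in enumerate(tables.values())]
    )
    Xm = counts.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    k = len(labels)
    acc = np.zeros((k, k))
    for fold, (tr, te) in enumerate(skf.split(Xm, y)):
        present = np.unique(y[tr])
        if len(present) < k:
            raise ValueError("a timepoint class is absent from a training fold")
        clf = RandomForestClassifier(
            n_estimators=params.n_trees,
            max_features="sqrt",
            random_state=params.seed + fold,
            n_jobs=1,
        )
        clf.fit(Xm[tr], y[tr])
        pred = clf.predict(Xm[te])
        cm = np.zeros((k, k))
        for t, p in zip(y[te], pred):
            cm[int(t), int(p)] += 1
        acc += cm / cm.sum(axis=1, keepdims=True)
    acc /= n_folds
    mat = pd.DataFrame(acc, index=labels, columns=labels)
    return ConfusionMatrix(
        matrix=mat,
        per_class_accuracy=pd.Series(np.diag(acc), index=labels),
        overall_accuracy=float(np.diag(acc).mean()),
    )
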