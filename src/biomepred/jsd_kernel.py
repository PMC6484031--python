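"""Jensen-Shannon distances and the 1 - JSD similarity kernel.

The Jensen-Shannon distance between two relative-abundance profiles a, b is

    D(a, b) = sqrt( (KL(a || m) + KL(b || m)) / 2 ),   m = (a + b) / 2,

with base-2 logarithms, so D lies in [0, 1] and reaches 1 exactly when the
supports are disjoint.  The similarity M = 1 - JSD serves as the covariance
of a random per-animal effect in kernel (RKHS) regression.  Because 1 - JSD
is not guaranteed positive semidefinite, an optional eigenvalue-clipping
repair is applied before use as a covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["KernelMatrix", "jsd_pair", "jsd_matrix", "kernel_from_jsd"]

_NORM_TOL = 1e-8


def _validate_composition(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if (x < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(x.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} does not sum to 1 (got {x.sum()!r})")
    return x


def _entropy2(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in bits with the 0*log0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(x > 0, x * np.log2(np.where(x > 0, x, 1.0)), 0.0)
    return -t.sum(axis=axis)


def jsd_pair(a, b) -> float:
    """Jensen-Shannon distance (base 2) between two compositions."""
    a = _validate_composition(a, "a")
    b = _validate_composition(b, "b")
    if a.shape != b.shape:
        raise ValueError("compositions have different lengths")
    m = 0.5 * (a + b)
    # JSD^2 = H(m) - (H(a) + H(b)) / 2, algebraically equal to the
    # averaged-KL form and immune to 0/0 at shared zeros.
    d2 = _entropy2(m) - 0.5 * (_entropy2(a) + _entropy2(b))
    return float(np.sqrt(max(d2, 0.0)))


def jsd_matrix(compositions) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distance matrix.

    Parameters
    ----------
    compositions
        DataFrame (samples x OTUs) or 2-D array of relative abundances;
        every row must sum to 1.

    Returns
    -------
    Symmetric DataFrame with zero diagonal and entries in [0, 1].
    """
    if isinstance(compositions, pd.DataFrame):
        ids = compositions.index
        P = compositions.to_numpy(dtype=float)
    else:
        P = np.asarray(compositions, dtype=float)
        ids = pd.RangeIndex(P.shape[0])
    if (P < 0).any():
        raise ValueError("negative entries in compositions")
    sums = P.sum(axis=1)
    if np.abs(sums - 1.0).max() > _NORM_TOL:
        raise ValueError("every composition row must sum to 1")
    n = P.shape[0]
    H = _entropy2(P, axis=1)
    D2 = np.zeros((n, n))
    for i in range(n):
        m = 0.5 * (P[i] + P[i:])
        D2[i, i:] = _entropy2(m, axis=1) - 0.5 * (H[i] + H[i:])
    D2 = np.maximum(D2 + np.triu(D2, 1).T, 0.0)
    D = np.sqrt(D2)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass
class KernelMatrix:
    """Similarity matrix M = 1 - JSD, optionally repaired to be PSD.

    Attributes
    ----------
    M
        Symmetric similarity matrix, unit diagonal.
    jsd
        The source distance matrix.
    repair
        Repair mode applied ("none", "clip" or "jitter").
    eigenvalue_floor
        Magnitude of the most negative eigenvalue removed by the repair
        (0 if none was needed or repair was "none").
    """

    M: pd.DataFrame
    jsd: pd.DataFrame
    repair: str
    eigenvalue_floor: float

    @property
    def sample_ids(self) -> pd.Index:
        return self.M.index

    def submatrix(self, rows, cols=None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.M.loc[pd.Index(rows), pd.Index(cols)].to_numpy()


def kernel_from_jsd(jsd: pd.DataFrame, repair: str = "clip") -> KernelMatrix:
    """Similarity kernel M = 1 - JSD with optional positive-semidefinite repair.

    repair="clip" floors negative eigenvalues at zero, reconstitutes the
    matrix and renormalizes so the diagonal is exactly 1; "jitter" adds the
    smallest diagonal shift making the minimum eigenvalue 0 and rescales;
    "none" returns the raw 1 - JSD.
    """
    if repair not in ("none", "clip", "jitter"):
        raise ValueError(f"unknown repair mode: {repair!r}")
    if isinstance(jsd, pd.DataFrame):
        ids = jsd.index
        D = jsd.to_numpy(dtype=float)
    else:
        D = np.asarray(jsd, dtype=float)
        ids = pd.RangeIndex(D.shape[0])
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("JSD matrix must be square and symmetric")
    M = 1.0 - D
    floor = 0.0
    if repair != "none":
        vals = np.linalg.eigvalsh(M)
        if vals[0] < 0:
            floor = float(-vals[0])
            if repair == "clip":
                w, V = np.linalg.eigh(M)
                M = (V * np.clip(w, 0.0, None)) @ V.T
            else:  # jitter
                M = M + floor * np.eye(M.shape[0])
            # renormalize to a correlation-like matrix with unit diagonal
            d = np.sqrt(np.clip(np.diag(M), 1e-12, None))
            M = M / np.outer(d, d)
            M = 0.5 * (M + M.T)
            np.fill_diagonal(M, 1.0)
    Mdf = pd.DataFrame(M, index=ids, columns=ids)
    jsd_df = pd.DataFrame(D, index=ids, columns=ids)
    return KernelMatrix(M=Mdf, jsd=jsd_df, repair=repair, eigenvalue_floor=floor)
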