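"""Constrained ordination core.

Redundancy analysis (RDA) is a PCA of the fitted values of a multivariate
linear regression: the genotype response matrix Y (individuals x loci) is
regressed on the predictor matrix X, and the canonical axes are the
principal axes of the fitted Y-hat.  Partial RDA residualizes both Y and X
on a conditioning matrix Z (e.g. population-structure axes) first.  The
module also provides standardization, Spearman collinearity screening, PCA,
the Ezekiel adjusted R-squared, a permutation pseudo-F test and
nested-model variance partitioning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("msgea")


class StandardizationError(ValueError):
    pass


class ModelError(ValueError):
    pass


def _as_array(m) -> np.ndarray:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float)
    return np.asarray(m, dtype=float)


def standardize(matrix):
    """Center each column to mean 0 and scale to unit sample SD (ddof=1).

    Raises :class:`StandardizationError` naming any constant column.
    """
    if isinstance(matrix, pd.DataFrame):
        arr = matrix.to_numpy(dtype=float)
        names = list(matrix.columns)
    else:
        arr = np.asarray(matrix, dtype=float)
        names = [str(i) for i in range(arr.shape[1])]
    sd = arr.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise StandardizationError(f"constant column(s): {[names[i] for i in bad]}")
    out = (arr - arr.mean(axis=0)) / sd
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def spearman_screen(env, threshold: float = 0.8):
    """Drop later columns of pairs with |Spearman r| >= ``threshold``.

    Columns are walked in their given priority order; a column is retained
    only if its rank correlation with every already-retained column stays
    below the threshold.  Returns (retained column names, correlation
    DataFrame, flagged pair list).
    """
    from .terrain import EnvironmentMatrix

    df = env.data if isinstance(env, EnvironmentMatrix) else pd.DataFrame(env)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 columns to screen")
    corr, _ = stats.spearmanr(df.to_numpy(dtype=float))
    if df.shape[1] == 2:  # scipy collapses the 2-column case to a scalar
        corr = np.array([[1.0, corr], [corr, 1.0]])
    corr = pd.DataFrame(corr, index=df.columns, columns=df.columns)
    retained: list[str] = []
    flagged: list[tuple[str, str, float]] = []
    for col in df.columns:
        hit = None
        for kept in retained:
            r = corr.loc[kept, col]
            if abs(r) >= threshold:
                hit = (kept, col, float(r))
                break
        if hit is None:
            retained.append(col)
        else:
            flagged.append(hit)
            logger.info("spearman screen: dropping %s (|r_s|=%.3f with %s)", col, abs(hit[2]), hit[0])
    return retained, corr, flagged


def pca(matrix, k: int):
    """PCA of the column-centered matrix via SVD.

    Returns (scores n x k, loadings p x k, eigenvalues length k) with
    eigenvalues = singular values squared / (n - 1), non-increasing.
    """
    X = _as_array(matrix)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    return (U * s)[:, :k], Vt.T[:, :k], eig[:k]


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2) (n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _residualize(M: np.ndarray, Q: np.ndarray | None) -> np.ndarray:
    """Residuals of the centered M on the orthonormal basis Q."""
    Mc = M - M.mean(axis=0)
    if Q is None or Q.shape[1] == 0:
        return Mc
    return Mc - Q @ (Q.T @ Mc)


def _orthonormal_basis(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the centered column space (rank-revealing SVD)."""
    Mc = M - M.mean(axis=0)
    if Mc.shape[1] == 0:
        return Mc
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    rank = int(np.sum(s > tol * max(s[0], 1.0))) if s.size else 0
    return U[:, :rank]


@dataclass
class RdaModel:
    """A fitted (partial) redundancy analysis.

    ``loadings`` are the locus weights on the canonical axes (columns of V
    from the SVD of Y-hat); ``site_scores`` are the constrained sample
    scores (U * s); ``biplot_scores`` are the correlations of each predictor
    with the site scores per axis.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    site_scores: np.ndarray
    biplot_scores: pd.DataFrame
    r2: float
    adj_r2: float
    n: int
    p: int
    cond_rank: int
    total_variance: float
    predictor_names: list[str]

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def summary_frame(self) -> pd.DataFrame:
        rows = {
            "eigenvalue": self.eigenvalues,
            "prop_explained": self.eigenvalues / self.eigenvalues.sum()
            if self.eigenvalues.sum() > 0
            else self.eigenvalues,
        }
        return pd.DataFrame(rows, index=[f"RDA{i+1}" for i in range(self.n_axes)])

    def to_report(self, path) -> None:
        """Plain-text header plus TSV blocks (axes, biplot scores)."""
        with open(path, "w") as fh:
            fh.write(
                f"# RDA model: n={self.n} individuals, p={self.p} predictors, "
                f"conditioning rank={self.cond_rank}\n"
                f"# R2 = {self.r2:.6f}\tadjusted R2 = {self.adj_r2:.6f}\n"
            )
            self.summary_frame().to_csv(fh, sep="\t", index_label="axis")
            fh.write("\n")
            self.biplot_scores.to_csv(fh, sep="\t", index_label="predictor")


def rda(Y, X, Z=None, allow_deficient: bool = False) -> RdaModel:
    """Fit an RDA of response Y on predictors X, optionally partialling Z.

    Y is centered (not scaled); if Z is given, Y and X are replaced by
    their residuals on Z.  Canonical eigenvalues are the PCA eigenvalues of
    the fitted values; R^2 is the fraction of the (conditioned) total
    variance they capture.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else None
    Ya, Xa = _as_array(Y), _as_array(X)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    if Ya.shape[0] != Xa.shape[0]:
        raise ModelError("Y and X must have the same number of rows")
    names = list(Xdf.columns) if Xdf is not None else [f"x{i}" for i in range(Xa.shape[1])]
    Za = None
    if Z is not None:
        Za = _as_array(Z)
        if Za.ndim == 1:
            Za = Za[:, None]
        if Za.shape[1] and Za.shape[0] != Ya.shape[0]:
            raise ModelError("Z must have the same number of rows as Y")
    n = Ya.shape[0]
    Qz = _orthonormal_basis(Za) if Za is not None and Za.shape[1] else None
    cond_rank = 0 if Qz is None else Qz.shape[1]

    Yr = _residualize(Ya, Qz)
    Xr = _residualize(Xa, Qz)
    sx = np.linalg.svd(Xr, compute_uv=False) if Xr.shape[1] else np.array([])
    rank_x = int(np.sum(sx > 1e-10 * max(sx[0], 1.0))) if sx.size else 0
    if rank_x < Xr.shape[1]:
        if Qz is None and not allow_deficient:
            # genuine collinearity among predictors is an error; under
            # conditioning, columns absorbed by Z legitimately lose rank
            raise ModelError(
                f"predictor matrix rank-deficient (rank {rank_x} < "
                f"{Xr.shape[1]} columns): {names}"
            )
        logger.debug("conditioning absorbed %d predictor dimensions", Xr.shape[1] - rank_x)
    Qx = _orthonormal_basis(Xr)
    Yhat = Qx @ (Qx.T @ Yr)
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    q = min(Qx.shape[1], n - 1, Yr.shape[1])
    eig = s[:q] ** 2 / (n - 1)
    # R^2 is reported against the full centered variance of Y, so that a
    # conditioned (partial) model's share shrinks as Z absorbs variance
    Yc_full = Ya - Ya.mean(axis=0)
    total = float(np.sum(Yc_full**2)) / (n - 1)
    r2 = float(eig.sum() / total) if total > 0 else 0.0
    site = U[:, :q] * s[:q]
    load = Vt.T[:, :q]
    # biplot scores: predictor / site-score correlations, nan-safe
    bip = np.zeros((Xr.shape[1], q))
    site_sd = site.std(axis=0)
    for j in range(Xr.shape[1]):
        xj = Xr[:, j]
        sd = xj.std()
        for a in range(q):
            if sd > 0 and site_sd[a] > 0:
                bip[j, a] = float(np.corrcoef(xj, site[:, a])[0, 1])
    adj = adjusted_r2(r2, n - cond_rank, rank_x) if n - cond_rank > rank_x + 1 else float("nan")
    return RdaModel(
        eigenvalues=eig,
        loadings=load,
        site_scores=site,
        biplot_scores=pd.DataFrame(bip, index=names, columns=[f"RDA{i+1}" for i in range(q)]),
        r2=r2,
        adj_r2=adj,
        n=n,
        p=rank_x,
        cond_rank=cond_rank,
        total_variance=total,
        predictor_names=names,
    )


def permutation_test(Y, X, Z=None, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Permutation pseudo-F test of X given Z (reduced-model permutation).

    The conditioned response rows are permuted; the statistic is
    F = (explained / p) / (residual / (n - p - 1 - rank(Z))).  Returns
    (p-value, observed F) with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    Ya, Xa = _as_array(Y), _as_array(X)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    Za = None
    if Z is not None:
        Za = _as_array(Z)
        if Za.ndim == 1:
            Za = Za[:, None]
        if Za.shape[1] == 0:
            Za = None
    n = Ya.shape[0]
    Qz = _orthonormal_basis(Za) if Za is not None else None
    rank_z = 0 if Qz is None else Qz.shape[1]
    Yr = _residualize(Ya, Qz)
    Xr = _residualize(Xa, Qz)
    Qx = _orthonormal_basis(Xr)
    p = Qx.shape[1]
    df_res = n - p - 1 - rank_z
    if df_res <= 0:
        raise ModelError("no residual degrees of freedom for the permutation test")
    total = np.sum(Yr**2)

    def pseudo_f(Ym: np.ndarray) -> float:
        expl = np.sum((Qx.T @ Ym) ** 2)
        resid = max(np.sum(Ym**2) - expl, 0.0)
        if resid == 0:
            return np.inf
        return (expl / p) / (resid / df_res)

    f_obs = pseudo_f(Yr)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(Yr[perm]) >= f_obs:
            count += 1
    pval = (1 + count) / (1 + n_perm)
    _ = total
    return pval, f_obs


def select_k_scree(eigenvalues, k_min: int = 2, k_max: int = 8) -> int:
    """Number of leading axes before the largest successive eigenvalue drop.

    The drop between axes i and i+1 is the ratio lambda_{i+1} / lambda_i;
    K is the (1-based) index before the smallest ratio, floored at
    ``k_min`` (two axes by default so outlier statistics stay multivariate).
    The elbow search is limited to the leading ``k_max`` axes: on saturated
    models the decaying tail (and the numerical null space) would otherwise
    masquerade as the scree drop.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    positive = eig[eig > 1e-10 * max(eig[0], 1.0)][: k_max + 1]
    if positive.size < 2:
        return min(k_min, eig.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = positive[1:] / positive[:-1]
    ratios = np.where(np.isfinite(ratios), ratios, 1.0)
    k = int(np.argmin(ratios)) + 1
    return min(max(k, min(k_min, positive.size)), k_max)


@dataclass
class PartitionResult:
    """Adjusted-R^2 fractions from three-block variance partitioning."""

    unique_env: float
    unique_structure: float
    unique_geography: float
    shared_env_structure: float
    shared_env_geography: float
    shared_structure_geography: float
    shared_all: float
    total: float
    residual: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "unique_env": self.unique_env,
                "unique_structure": self.unique_structure,
                "unique_geography": self.unique_geography,
                "shared_env_structure": self.shared_env_structure,
                "shared_env_geography": self.shared_env_geography,
                "shared_structure_geography": self.shared_structure_geography,
                "shared_all": self.shared_all,
                "total": self.total,
                "residual": self.residual,
            }
        )


def variance_partition(Y, env, structure, geography) -> PartitionResult:
    """Partition Y's variance over three predictor blocks.

    Fits the seven nested RDA models (every non-empty subset of the blocks)
    and combines their Ezekiel-adjusted R^2 by inclusion-exclusion into
    unique and shared fractions; the residual is one minus the full-model
    adjusted R^2.
    """
    blocks = {"E": _as_array(env), "S": _as_array(structure), "G": _as_array(geography)}
    for k, v in blocks.items():
        if v.ndim == 1:
            blocks[k] = v[:, None]
    adj: dict[frozenset, float] = {frozenset(): 0.0}
    for r in (1, 2, 3):
        for combo in itertools.combinations("ESG", r):
            X = np.hstack([blocks[c] for c in combo])
            adj[frozenset(combo)] = rda(Y, X).adj_r2
    a = lambda *cs: adj[frozenset(cs)]
    full = a("E", "S", "G")
    uE = full - a("S", "G")
    uS = full - a("E", "G")
    uG = full - a("E", "S")
    # pairwise overlaps including the triple, then peel the triple off
    sES_t = a("E") + a("S") - a("E", "S")
    sEG_t = a("E") + a("G") - a("E", "G")
    sSG_t = a("S") + a("G") - a("S", "G")
    triple = a("E") + a("S") + a("G") - a("E", "S") - a("E", "G") - a("S", "G") + full
    sES = sES_t - triple
    sEG = sEG_t - triple
    sSG = sSG_t - triple
    return PartitionResult(
        unique_env=uE,
        unique_structure=uS,
        unique_geography=uG,
        shared_env_structure=sES,
        shared_env_geography=sEG,
        shared_structure_geography=sSG,
        shared_all=triple,
        total=full,
        residual=1.0 - full,
    )
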