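"""Outlier locus detection from RDA loadings.

Each locus is summarized by its loadings on the K retained canonical axes.
A robust Mahalanobis distance locates loci far from the bulk of the
loading cloud; distances are rescaled by a genomic inflation factor
(median observed / median chi-squared with K degrees of freedom), converted
to upper-tail chi-squared p-values and thresholded with a Bonferroni
family-wise cutoff of alpha / m.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("msgea")


class EstimationError(ValueError):
    pass


def robust_mahalanobis(loadings, method: str = "mcd", seed: int = 0) -> np.ndarray:
    """Squared Mahalanobis distances of loci in K-axis loading space.

    ``mcd`` uses the minimum-covariance-determinant estimator (75% subset)
    so planted outliers do not drag the scatter estimate; ``classical``
    uses the sample mean and covariance.  MCD falls back to classical when
    the locus count is too small (< 5K) or the robust scatter is singular.
    """
    X = np.asarray(loadings, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if k < 1:
        raise ValueError("need at least one axis")
    if n <= 5 * k:
        raise ValueError(f"need more than 5*K={5 * k} loci, got {n}")
    if method not in ("mcd", "classical"):
        raise ValueError(f"unknown method {method!r}")
    if method == "mcd":
        from sklearn.covariance import MinCovDet

        try:
            est = MinCovDet(support_fraction=0.75, random_state=seed).fit(X)
            cov, loc = est.covariance_, est.location_
            if np.linalg.matrix_rank(cov) < k:
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("MCD failed or singular; falling back to classical estimate")
            method = "classical"
    if method == "classical":
        loc = X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
        cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(np.atleast_2d(cov)) < k:
        raise EstimationError("singular scatter matrix")
    prec = np.linalg.inv(np.atleast_2d(cov))
    diff = X - loc
    return np.einsum("ij,jk,ik->i", diff, prec, diff)


def genomic_inflation(d2, k: int) -> float:
    """Inflation factor: median(D^2) / median of chi-squared_K."""
    d2 = np.asarray(d2, dtype=float)
    if d2.size == 0:
        raise ValueError("empty distance vector")
    return float(np.median(d2) / stats.chi2.median(df=k))


def loadings_pvalues(d2, lam: float, k: int) -> np.ndarray:
    """Upper-tail chi-squared_K p-values of the inflation-corrected D^2."""
    if lam <= 0:
        raise ValueError("inflation factor must be positive")
    return stats.chi2.sf(np.asarray(d2, dtype=float) / lam, df=k)


def bonferroni_threshold(m: int, alpha: float = 0.01) -> float:
    """Family-wise threshold alpha / m for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class OutlierTable:
    """Per-locus scan results plus the shared scan constants."""

    table: pd.DataFrame  # locus_id, chrom, pos, category, D2, p, outlier
    k: int
    inflation: float
    threshold: float

    @property
    def outlier_ids(self) -> list[str]:
        return self.table.loc[self.table["outlier"], "locus_id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def detect_outliers(
    p,
    threshold: float,
    loci: pd.DataFrame,
    d2=None,
    k: int = 0,
    inflation: float = float("nan"),
) -> OutlierTable:
    """Flag loci with p strictly below ``threshold``; annotate categories."""
    p = np.asarray(p, dtype=float)
    if len(loci) != p.size:
        raise ValueError("locus metadata and p-vector lengths differ")
    table = loci[["locus_id", "chrom", "pos", "category"]].copy().reset_index(drop=True)
    table["gene_id"] = loci["gene_id"].to_numpy() if "gene_id" in loci else None
    table["D2"] = np.asarray(d2, dtype=float) if d2 is not None else np.nan
    table["p"] = p
    table["outlier"] = p < threshold
    n_out = int(table["outlier"].sum())
    n_hi = int((table["outlier"] & (table["category"] == "high_impact")).sum())
    logger.info(
        "detect_outliers: %d/%d outliers at p < %.3g (%d high-impact)",
        n_out, p.size, threshold, n_hi,
    )
    return OutlierTable(table=table, k=k, inflation=inflation, threshold=threshold)


def scan_loadings(
    loadings,
    loci: pd.DataFrame,
    k: int,
    alpha: float = 0.01,
    method: str = "mcd",
    seed: int = 0,
) -> OutlierTable:
    """Full scan: D^2 on the first ``k`` axes -> inflation -> p -> Bonferroni."""
    X = np.asarray(loadings, dtype=float)[:, :k]
    try:
        d2 = robust_mahalanobis(X, method=method, seed=seed)
    except ValueError:
        d2 = robust_mahalanobis(X, method="classical", seed=seed)
    lam = genomic_inflation(d2, k)
    p = loadings_pvalues(d2, lam, k)
    thr = bonferroni_threshold(X.shape[0], alpha)
    out = detect_outliers(p, thr, loci, d2=d2, k=k, inflation=lam)
    return out


def compute_ps(outliers: OutlierTable, high_impact_ids) -> float:
    """Proportion of the high-impact SNP set flagged as outliers (p_S)."""
    high = set(high_impact_ids)
    if not high:
        raise ValueError("high-impact set is empty; p_S undefined")
    return len(set(outliers.outlier_ids) & high) / len(high)


def compare_outlier_sets(named_sets: dict[str, set]) -> pd.DataFrame:
    """Upset-style exclusive intersection sizes over >= 2 named sets.

    One row per non-empty subset of set names, counting the elements
    belonging to exactly those sets, plus each set's unique fraction.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets to compare")
    names = list(named_sets)
    sets = {n: set(s) for n, s in named_sets.items()}
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            exclusive = inside - outside
            rows.append({"sets": "&".join(combo), "degree": r, "count": len(exclusive)})
    df = pd.DataFrame(rows)
    uniq = {}
    for n in names:
        others = set.union(set(), *(sets[m] for m in names if m != n))
        only = sets[n] - others
        uniq[n] = len(only) / len(sets[n]) if sets[n] else 0.0
    df.attrs["unique_fractions"] = uniq
    return df
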