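"""Assigning outlier loci to driving environmental variables.

Each outlier locus lives in the K-axis ordination space through its
loading vector; each predictor lives there through its biplot scores.  The
locus is assigned to the predictor with the largest absolute scalar
projection of the loading vector onto the (unit-normalized) predictor
vector.  Gene tallies aggregate SNP-variable associations per gene, and a
fitted logistic cline maps the probability of a genotype class across a
variable raster.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .terrain import Raster

logger = logging.getLogger("msgea")

GENOTYPE_CLASSES = {"hom_ref": 0.0, "het": 1.0, "hom_alt": 2.0}


def assign_variable(
    loadings,
    biplot: pd.DataFrame,
    outlier_index,
    normalize: bool = False,
) -> pd.Series:
    """Assign each outlier locus to the predictor with the largest
    absolute projection in ordination space.

    ``loadings`` is loci x K, ``biplot`` predictors x K (index = predictor
    names), ``outlier_index`` the integer rows of the outlier loci.  With
    standardized predictors the biplot-score length measures how well a
    predictor is represented on the retained axes, so raw vectors are used
    by default: among nearly-parallel arrows the best-represented predictor
    wins the argmax.  ``normalize=True`` switches to pure-direction
    projection.  Zero-length vectors are excluded with a warning; ties
    break by predictor order.
    """
    L = np.asarray(loadings, dtype=float)
    B = biplot.to_numpy(dtype=float)
    if L.shape[1] != B.shape[1]:
        raise ValueError("loadings and biplot scores must share the axis count")
    norms = np.linalg.norm(B, axis=1)
    usable = norms > 0
    if not usable.all():
        dropped = [biplot.index[i] for i in np.where(~usable)[0]]
        warnings.warn(f"zero-length biplot vectors excluded: {dropped}")
    if not usable.any():
        raise ValueError("no usable predictor vectors")
    Bu = B[usable]
    if normalize:
        Bu = Bu / np.linalg.norm(Bu, axis=1, keepdims=True)
    names = [n for n, u in zip(biplot.index, usable) if u]
    idx = np.asarray(outlier_index, dtype=int)
    proj = L[idx] @ Bu.T  # outliers x predictors
    best = np.argmax(np.abs(proj), axis=1)  # argmax takes the first on ties
    return pd.Series([names[b] for b in best], index=idx, name="assigned_variable")


def gene_tally(assignments: pd.Series, locus_genes: pd.Series) -> pd.DataFrame:
    """Per-gene table of SNP-variable associations.

    ``assignments`` maps locus row -> variable, ``locus_genes`` locus row ->
    gene id.  A gene whose outlier SNPs all share one variable gets that
    variable; genes hit by several variables are marked ``multiple``.
    Genes without outlier SNPs are absent.
    """
    df = pd.DataFrame(
        {"gene_id": locus_genes.loc[assignments.index], "variable": assignments}
    ).dropna(subset=["gene_id"])
    rows = []
    for gene, grp in df.groupby("gene_id", sort=True):
        variables = sorted(set(grp["variable"]))
        rows.append(
            {
                "gene_id": gene,
                "variable": variables[0] if len(variables) == 1 else "multiple",
                "n_snps": len(grp),
                "n_variables": len(variables),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "variable", "n_snps", "n_variables"])


def genotype_probability_map(
    dosages,
    genotype_class: str,
    variable_raster: Raster,
    variable_at_samples,
    l2_penalty: float = 1e-4,
) -> tuple[Raster, pd.Series]:
    """Map the probability of a genotype class across a variable raster.

    Fits a logistic regression of the binary class indicator (one locus's
    dosages) on the standardized variable, then applies the fitted curve
    cell-wise.  A small L2 penalty keeps coefficients finite under perfect
    separation.  Returns (probability raster, coefficient series).
    """
    if genotype_class not in GENOTYPE_CLASSES:
        raise ValueError(f"unknown genotype class {genotype_class!r}")
    dos = np.asarray(dosages, dtype=float)
    x = np.asarray(variable_at_samples, dtype=float)
    if dos.size != x.size:
        raise ValueError("dosages and variable values must align")
    if dos.size < 10:
        raise ValueError("need at least 10 samples for the logistic fit")
    y = (dos == GENOTYPE_CLASSES[genotype_class]).astype(int)
    if y.min() == y.max():
        raise ValueError(f"class {genotype_class!r} absent or universal; fit refused")
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        raise ValueError("variable is constant at the samples")
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / l2_penalty, solver="lbfgs", max_iter=1000)
    clf.fit(((x - mu) / sd)[:, None], y)
    beta = float(clf.coef_[0, 0])
    alpha = float(clf.intercept_[0])
    z = (variable_raster.values - mu) / sd
    prob = 1.0 / (1.0 + np.exp(-(alpha + beta * z)))
    prob = np.where(variable_raster.mask, np.nan, prob)
    out = Raster(
        prob,
        origin=variable_raster.origin,
        cell_size=variable_raster.cell_size,
        mask=variable_raster.mask.copy(),
    )
    coefs = pd.Series(
        {"intercept": alpha, "slope": beta, "mean": mu, "sd": sd, "n": dos.size}
    )
    logger.info(
        "genotype_probability_map: %s ~ logistic(%.3f + %.3f z), n=%d",
        genotype_class, alpha, beta, dos.size,
    )
    return out, coefs
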