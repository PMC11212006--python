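"""SNP genotype reading, filtering, imputation, LD pruning, partitioning.

Genotypes are held as alternate-allele dosages (0/1/2) in an
individuals x loci float matrix with NaN marking missing calls.  Locus
metadata carries the annotation category used downstream: ``intergenic``
loci are treated as putatively neutral (population-structure proxies),
``intragenic`` loci are the GEA response, and ``high_impact`` is the
within-gene subcategory of intragenic loci with predicted functional
effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("msgea")

CATEGORIES = ("intergenic", "intragenic", "high_impact")

LOCUS_COLUMNS = ["locus_id", "chrom", "pos", "category", "gene_id"]


class FormatError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele dosages with locus metadata.

    ``dosages`` is float with values in {0, 1, 2, NaN}; ``loci`` is a
    DataFrame with columns ``locus_id, chrom, pos, category, gene_id``
    aligned to the dosage columns.
    """

    dosages: np.ndarray
    samples: list[str]
    loci: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=LOCUS_COLUMNS))

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample count mismatch")
        self.loci = self.loci.reset_index(drop=True)
        if len(self.loci) != self.dosages.shape[1]:
            raise ValueError("locus metadata count mismatch")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.where(index)[0]
        return GenotypeMatrix(
            self.dosages[:, index], list(self.samples), self.loci.iloc[index]
        )

    # -- plain-text dosage interchange -------------------------------------

    def to_tsv(self, path) -> None:
        """Loci as rows: metadata columns then one dosage column per sample."""
        meta = self.loci.copy()
        dos = pd.DataFrame(self.dosages.T, columns=self.samples)
        pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
            path, sep="\t", index=False, na_rep="NA"
        )

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        missing_meta = [c for c in LOCUS_COLUMNS if c not in df.columns]
        if missing_meta:
            raise FormatError(f"dosage TSV lacks columns: {missing_meta}")
        samples = [c for c in df.columns if c not in LOCUS_COLUMNS]
        dosages = df[samples].to_numpy(dtype=float).T
        return cls(dosages, samples, df[LOCUS_COLUMNS])


def read_annotations(path) -> pd.DataFrame:
    """Locus annotation TSV: locus_id, chrom, pos, category, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chrom": str, "gene_id": str})
    missing = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table lacks columns: {missing}")
    bad = set(df["category"].dropna()) - set(CATEGORIES)
    if bad:
        raise AnnotationError(f"unknown categories: {sorted(bad)}")
    return df


def attach_annotations(gm: GenotypeMatrix, annotations: pd.DataFrame) -> GenotypeMatrix:
    """Replace locus categories / gene ids by matching ``locus_id``."""
    ann = annotations.set_index("locus_id")
    loci = gm.loci.copy()
    unmatched = set(loci["locus_id"]) - set(ann.index)
    if unmatched:
        raise AnnotationError(f"loci without annotation: {sorted(unmatched)[:5]} ...")
    loci["category"] = loci["locus_id"].map(ann["category"]).to_numpy()
    loci["gene_id"] = loci["locus_id"].map(ann["gene_id"]).to_numpy()
    return GenotypeMatrix(gm.dosages, list(gm.samples), loci)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(
                f"non-biallelic record at {var.CHROM}:{var.POS} (ALT={var.ALT})"
            )
        dos = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if alleles:
                dos[i] = float(sum(alleles))
        rows.append(dos)
        locus_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        meta.append((locus_id, var.CHROM, var.POS, "intragenic", None))
    loci = pd.DataFrame(meta, columns=LOCUS_COLUMNS)
    return GenotypeMatrix(np.array(rows).T, samples, loci)


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT fields) or a dosage TSV."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return GenotypeMatrix.from_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF v4.2 with GT fields (A/T alleles)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, row in gm.loci.iterrows():
            gts = [
                gt_map.get(gm.dosages[i, j], "./.") for i in range(gm.n_samples)
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['locus_id']}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering / imputation / pruning / partitioning
# ---------------------------------------------------------------------------

def filter_snps(
    gm: GenotypeMatrix, maf_min: float = 0.025, max_missing: float = 0.10
) -> GenotypeMatrix:
    """Drop loci with MAF strictly below ``maf_min`` (from non-missing
    calls) or missing fraction strictly above ``max_missing``."""
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    maf = gm.maf()
    miss = gm.missing_fraction()
    all_missing = np.isnan(maf)
    keep = ~all_missing & (maf >= maf_min) & (miss <= max_missing)
    n_maf = int(np.sum(~all_missing & (maf < maf_min)))
    n_miss = int(np.sum(miss > max_missing))
    logger.info(
        "filter_snps: kept %d/%d loci (%d below MAF %.3f, %d above missingness %.2f)",
        keep.sum(), gm.n_loci, n_maf, maf_min, n_miss, max_missing,
    )
    if keep.sum() == 0:
        logger.warning("filter_snps: no loci survive filtering")
    return gm.subset_loci(keep)


def impute_missing(gm: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Draw each missing dosage as Binomial(2, p-hat) with p-hat the locus's
    observed alternate-allele frequency.  Observed dosages are untouched."""
    dos = gm.dosages.copy()
    missing = np.isnan(dos)
    if not missing.any():
        return gm
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = gm.loci.loc[np.where(all_missing)[0], "locus_id"].tolist()
        raise ValueError(f"cannot impute entirely-missing loci: {bad[:5]}")
    rng = np.random.default_rng(seed)
    p = gm.allele_freq()
    for j in np.where(missing.any(axis=0))[0]:
        rows = np.where(missing[:, j])[0]
        dos[rows, j] = rng.binomial(2, p[j], size=rows.size)
    return GenotypeMatrix(dos, list(gm.samples), gm.loci)


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.2, window: int = 50) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within a sliding window per chromosome.

    A locus is dropped when its squared dosage correlation with any
    already-retained locus among the previous ``window`` retained loci of
    the same chromosome exceeds ``r2_max``.  Missing calls are mean-imputed
    for the correlation only.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    dos = gm.dosages.copy()
    col_mean = np.nanmean(dos, axis=0)
    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(col_mean, inds[1])
    keep: list[int] = []
    chroms = gm.loci["chrom"].to_numpy()
    retained_by_chrom: dict[str, list[int]] = {}
    for j in range(gm.n_loci):
        prior = retained_by_chrom.setdefault(chroms[j], [])
        drop = False
        xj = dos[:, j]
        sj = xj.std()
        for k in prior[-window:]:
            xk = dos[:, k]
            sk = xk.std()
            if sj == 0 or sk == 0:
                r2 = 1.0 if sj == sk else 0.0
            else:
                r = np.corrcoef(xj, xk)[0, 1]
                r2 = r * r
            if r2 > r2_max:
                drop = True
                break
        if not drop:
            prior.append(j)
            keep.append(j)
    logger.info("ld_prune: retained %d/%d loci (r2 <= %.2f)", len(keep), gm.n_loci, r2_max)
    return gm.subset_loci(np.array(keep, dtype=int))


def partition_by_annotation(
    gm: GenotypeMatrix,
) -> tuple[GenotypeMatrix, GenotypeMatrix, list[str]]:
    """Split into (intergenic, intragenic, high-impact id list).

    High-impact loci are a subcategory of intragenic: they appear in the
    intragenic matrix and are additionally listed by id.
    """
    cats = gm.loci["category"]
    if cats.isna().any():
        bad = gm.loci.loc[cats.isna(), "locus_id"].tolist()
        raise AnnotationError(f"loci lacking a category: {bad[:5]}")
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise AnnotationError(f"unknown categories: {sorted(unknown)}")
    inter = gm.subset_loci((cats == "intergenic").to_numpy())
    intra = gm.subset_loci(cats.isin(["intragenic", "high_impact"]).to_numpy())
    high = gm.loci.loc[cats == "high_impact", "locus_id"].tolist()
    return inter, intra, high
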