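"""Synthetic study systems for the multiscale GEA pipeline.

Emulates the data a field study of a patchily-sampled alpine plant would
deposit: a fine-grained DEM with tunable ruggedness, clustered plot-based
sampling, SNP genotypes with Balding-Nichols population structure plus
planted loci whose allele frequencies follow logistic clines in a chosen
terrain variable at a chosen resolution, and gene/GO annotations.  Every
generator is a pure function of its seed and arguments, so downstream
modules have a deterministic no-download test surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io, terrain
from .terrain import EnvironmentMatrix, Raster, TerrainParams, column_name

logger = logging.getLogger("msgea")


class GenerationError(RuntimeError):
    """Sampling or simulation could not satisfy its constraints."""


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

def generate_dem(
    n_rows: int,
    n_cols: int,
    cell_size: float,
    ruggedness: float,
    trend_gradient: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    spectral_exponent: float = 2.5,
    base_elevation: float = 2000.0,
) -> Raster:
    """Planar trend plus a spectral-synthesis fractal surface.

    The stochastic part is inverse-FFT synthesis with a power-law spectrum
    (power ~ f^-``spectral_exponent``); its standard deviation in metres is
    ``ruggedness``, so zero ruggedness yields a purely planar raster.
    Deterministic given ``seed``.
    """
    if n_rows < 16 or n_cols < 16:
        raise ValueError("DEM must be at least 16x16")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if ruggedness < 0:
        raise ValueError("ruggedness must be non-negative")
    rng = np.random.default_rng(seed)
    gx, gy = trend_gradient
    xs = (np.arange(n_cols) + 0.5) * cell_size
    ys = -(np.arange(n_rows) + 0.5) * cell_size  # rows run southward
    z = base_elevation + gx * xs[None, :] + gy * ys[:, None]
    z = np.broadcast_to(z, (n_rows, n_cols)).astype(float).copy()
    if ruggedness > 0:
        fi = np.fft.fftfreq(n_rows)[:, None]
        fj = np.fft.fftfreq(n_cols)[None, :]
        f = np.hypot(fi, fj)
        with np.errstate(divide="ignore"):
            amp = np.where(f > 0, f ** (-spectral_exponent / 2.0), 0.0)
        noise = rng.normal(size=(n_rows, n_cols)) + 1j * rng.normal(size=(n_rows, n_cols))
        surf = np.real(np.fft.ifft2(amp * noise))
        sd = surf.std()
        if sd > 0:
            z += surf * (ruggedness / sd)
    return Raster(z, origin=(0.0, 0.0), cell_size=cell_size)


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingDesign:
    """Clustered plot-based sampling: plots of nearby individuals.

    Defaults mirror a typical alpine collection: 10 plots of 6-10
    individuals each, at least 1 m apart, within ``plot_spread`` metres of
    their plot center.  ``margin_frac`` keeps plots away from the raster
    edge so coarse-resolution derived cells stay valid at every sample.
    """

    n_plots: int = 10
    individuals_min: int = 6
    individuals_max: int = 10
    min_separation: float = 1.0
    plot_spread: float = 15.0
    margin_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.individuals_min > self.individuals_max:
            raise ValueError("invalid individuals-per-plot range")


def place_samples(dem: Raster, design: SamplingDesign, seed: int = 0) -> pd.DataFrame:
    """Sample coordinates honoring the plot design.

    Returns a table with ``sample_id, x, y, site`` where ``site`` is the
    plot label.  Raises :class:`GenerationError` when the pairwise
    separation constraint cannot be packed after bounded retries.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = dem.bounds
    mx = (xmax - xmin) * design.margin_frac
    my = (ymax - ymin) * design.margin_frac
    lo = np.array([xmin + mx, ymin + my])
    hi = np.array([xmax - mx, ymax - my])
    if np.any(hi <= lo):
        raise GenerationError("margin leaves no interior area to sample")

    centers: list[np.ndarray] = []
    for _ in range(design.n_plots):
        for _attempt in range(1000):
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - o) >= design.plot_spread for o in centers):
                centers.append(c)
                break
        else:
            raise GenerationError("could not disperse plot centers; shrink plot_spread")

    points: list[np.ndarray] = []
    rows = []
    idx = 0
    for k, c in enumerate(centers):
        n_ind = int(rng.integers(design.individuals_min, design.individuals_max + 1))
        for _ in range(n_ind):
            for _attempt in range(1000):
                r = design.plot_spread * math.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * math.pi)
                p = c + r * np.array([math.cos(th), math.sin(th)])
                inside = np.all(p >= lo) and np.all(p <= hi)
                if inside and all(
                    np.linalg.norm(p - q) >= design.min_separation for q in points
                ):
                    points.append(p)
                    rows.append(
                        {
                            "sample_id": f"s{idx:03d}",
                            "x": float(p[0]),
                            "y": float(p[1]),
                            "site": f"plot{k:02d}",
                        }
                    )
                    idx += 1
                    break
            else:
                raise GenerationError(
                    f"could not place an individual in plot {k} with "
                    f"min_separation={design.min_separation}"
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """The planted architecture of a simulated genotype matrix.

    ``driving_variable`` and ``effect_slope`` are per planted locus;
    ``planted_locus_ids`` is filled in by :func:`simulate_genotypes`.
    ``fst`` controls Balding-Nichols structure intensity across the
    ``n_pops`` populations; ``inbreeding`` inflates homozygosity the way
    partial selfing would.
    """

    driving_variable: list[tuple[str, float]]
    effect_slope: list[float]
    intercept: float = 0.0
    fst: float = 0.05
    n_pops: int = 10
    seed: int = 0
    inbreeding: float = 0.0
    planted_locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.driving_variable) != len(self.effect_slope):
            raise ValueError("driving_variable and effect_slope lengths differ")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not all(np.isfinite(self.effect_slope)):
            raise ValueError("effect slopes must be finite")

    @property
    def n_planted(self) -> int:
        return len(self.effect_slope)

    @classmethod
    def uniform(
        cls,
        n_planted: int,
        variable: str = "VRM",
        resolution: float = 2.0,
        beta: float = 2.0,
        **kwargs,
    ) -> "SyntheticTruth":
        return cls(
            driving_variable=[(variable, float(resolution))] * n_planted,
            effect_slope=[float(beta)] * n_planted,
            **kwargs,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.planted_locus_ids,
                "variable": [v for v, _ in self.driving_variable],
                "resolution_m": [r for _, r in self.driving_variable],
                "beta": self.effect_slope,
            }
        )


def _draw_dosage(rng, p, inbreeding: float) -> np.ndarray:
    """Genotypes with inbreeding F: the second allele copies the first
    with probability F, inflating homozygotes (P(het) scaled by 1 - F)."""
    p = np.asarray(p, dtype=float)
    a1 = rng.uniform(size=p.shape) < p
    copy = rng.uniform(size=p.shape) < inbreeding
    a2 = np.where(copy, a1, rng.uniform(size=p.shape) < p)
    return (a1.astype(float) + a2.astype(float))


#: fraction of neutral loci labelled intergenic; the rest are intragenic,
#: of which ``HIGH_IMPACT_FRACTION`` are flagged high-impact
INTERGENIC_FRACTION = 0.5
HIGH_IMPACT_FRACTION = 0.4
LOCI_PER_GENE = 2
N_CHROMOSOMES = 8


def simulate_genotypes(
    env: EnvironmentMatrix,
    truth: SyntheticTruth,
    n_neutral: int,
    missing_rate: float = 0.0,
    populations=None,
) -> tuple[genotype_io.GenotypeMatrix, SyntheticTruth]:
    """Neutral Balding-Nichols loci plus planted environmental clines.

    Neutral locus j: an ancestral frequency is drawn uniform on (0.1, 0.9),
    population frequencies follow Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``truth.fst``, and individual dosages are binomial draws from their
    population's frequency.  Planted locus l: dosages are binomial with
    per-individual probability logistic(alpha + beta * z) where z is the
    individual's standardized value of the driving variable.  Missing
    entries are masked uniformly at ``missing_rate``.  Neutral loci are
    labelled intergenic or intragenic (some intragenic high-impact);
    planted loci are always high-impact.  Gene ids and category metadata
    are attached; the returned truth carries the planted locus ids.
    """
    if not 0.0 <= missing_rate <= 0.5:
        raise ValueError("missing_rate must be in [0, 0.5]")
    df = env.data
    n_ind = len(df)
    zcols = {}
    for vtype, res in set(truth.driving_variable):
        name = column_name(vtype, res)
        if name not in df.columns:
            raise ConfigurationError(
                f"driving variable column {name!r} absent from the environment matrix"
            )
        col = df[name].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if sd == 0:
            raise ConfigurationError(f"driving variable {name!r} is constant")
        zcols[(vtype, res)] = (col - col.mean()) / sd

    rng = np.random.default_rng(truth.seed)
    if populations is None:
        populations = np.zeros(n_ind, dtype=int)
        n_pops = 1
    else:
        _, populations = np.unique(np.asarray(populations), return_inverse=True)
        n_pops = populations.max() + 1

    # neutral loci
    neutral = np.empty((n_ind, n_neutral))
    anc = rng.uniform(0.1, 0.9, size=n_neutral)
    if truth.fst > 0:
        a = anc * (1 - truth.fst) / truth.fst
        b = (1 - anc) * (1 - truth.fst) / truth.fst
        pop_freq = rng.beta(a, b, size=(n_pops, n_neutral))
    else:
        pop_freq = np.broadcast_to(anc, (n_pops, n_neutral))
    for j in range(n_neutral):
        neutral[:, j] = _draw_dosage(rng, pop_freq[populations, j], truth.inbreeding)

    # planted loci
    planted = np.empty((n_ind, truth.n_planted))
    for l in range(truth.n_planted):
        z = zcols[truth.driving_variable[l]]
        p = 1.0 / (1.0 + np.exp(-(truth.intercept + truth.effect_slope[l] * z)))
        planted[:, l] = _draw_dosage(rng, p, truth.inbreeding)

    # locus bookkeeping: planted loci scattered among the neutral ones
    n_total = n_neutral + truth.n_planted
    planted_pos = np.sort(rng.choice(n_total, size=truth.n_planted, replace=False))
    dosages = np.empty((n_ind, n_total))
    is_planted = np.zeros(n_total, dtype=bool)
    is_planted[planted_pos] = True
    dosages[:, is_planted] = planted
    dosages[:, ~is_planted] = neutral

    categories = np.empty(n_total, dtype=object)
    neutral_idx = np.where(~is_planted)[0]
    n_intergenic = int(round(INTERGENIC_FRACTION * n_neutral))
    cat_pool = np.array(
        ["intergenic"] * n_intergenic + ["intragenic"] * (n_neutral - n_intergenic),
        dtype=object,
    )
    rng.shuffle(cat_pool)
    intra_neutral = np.where(cat_pool == "intragenic")[0]
    n_hi = int(round(HIGH_IMPACT_FRACTION * intra_neutral.size))
    hi_choice = rng.choice(intra_neutral, size=n_hi, replace=False)
    cat_pool[hi_choice] = "high_impact"
    categories[neutral_idx] = cat_pool
    categories[is_planted] = "high_impact"

    per_chrom = math.ceil(n_total / N_CHROMOSOMES)
    chroms = [f"chr{(j // per_chrom) + 1}" for j in range(n_total)]
    pos = [(j % per_chrom) * 100 + 1 for j in range(n_total)]
    locus_ids = [f"L{j:05d}" for j in range(n_total)]
    gene_ids: list[str | None] = []
    gene_counter = 0
    run = 0
    for j in range(n_total):
        if categories[j] == "intergenic":
            gene_ids.append(None)
        else:
            gene_ids.append(f"gene{gene_counter:04d}")
            run += 1
            if run >= LOCI_PER_GENE:
                gene_counter += 1
                run = 0

    if missing_rate > 0:
        mask = rng.uniform(size=dosages.shape) < missing_rate
        dosages[mask] = np.nan

    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chrom": chroms,
            "pos": pos,
            "category": categories,
            "gene_id": gene_ids,
        }
    )
    gm = genotype_io.GenotypeMatrix(dosages, list(df.index.astype(str)), loci)
    truth.planted_locus_ids = [locus_ids[j] for j in planted_pos]
    logger.info(
        "simulated %d individuals x %d loci (%d planted, fst=%.3f, %d pops)",
        n_ind, n_total, truth.n_planted, truth.fst, n_pops,
    )
    return gm, truth


def generate_go_map(gene_ids, seed: int = 0, n_terms: int = 30) -> pd.DataFrame:
    """Random gene -> GO assignments (1-3 terms per gene) from a term pool."""
    rng = np.random.default_rng(seed)
    genes = sorted({g for g in gene_ids if g is not None and not pd.isna(g)})
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    namespaces = ["BP" if i % 2 == 0 else "MF" for i in range(n_terms)]
    rows = []
    for g in genes:
        k = int(rng.integers(1, 4))
        for t in rng.choice(n_terms, size=k, replace=False):
            rows.append({"gene_id": g, "go_id": terms[t], "namespace": namespaces[t]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end fixture
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    dem: Raster
    samples: pd.DataFrame
    env: EnvironmentMatrix
    genotypes: genotype_io.GenotypeMatrix
    truth: SyntheticTruth
    go_map: pd.DataFrame
    stack: terrain.MultiscaleStack


#: terrain settings used for fixtures: a shorter scan radius than the
#: field default, appropriate to the ~128 m synthetic extent
FIXTURE_TERRAIN = TerrainParams(scan_radius=30.0)


def generate_fixture(
    seed: int = 0,
    n_rows: int = 256,
    n_cols: int = 256,
    cell_size: float = 0.5,
    ruggedness: float = 1.5,
    trend_gradient: tuple[float, float] = (0.1, 0.05),
    design: SamplingDesign = SamplingDesign(),
    n_neutral: int = 2000,
    n_planted: int = 20,
    beta: float = 2.0,
    fst: float = 0.05,
    missing_rate: float = 0.05,
    driving_variable: str = "VRM",
    driving_resolution: float = 2.0,
    resolutions=terrain.DEFAULT_RESOLUTIONS,
    params: TerrainParams = FIXTURE_TERRAIN,
) -> Fixture:
    """One fully-wired synthetic study site.

    DEM -> terrain stack -> plot-based samples -> extracted environment ->
    genotypes with planted clines in ``driving_variable`` at
    ``driving_resolution``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))
    dem = generate_dem(
        n_rows, n_cols, cell_size, ruggedness, trend_gradient, seed=sub()
    )
    stack = terrain.derive_stack(dem, resolutions=resolutions, params=params)
    samples = place_samples(dem, design, seed=sub())
    env = terrain.extract_at_points(stack, samples)
    truth = SyntheticTruth.uniform(
        n_planted,
        variable=driving_variable,
        resolution=driving_resolution,
        beta=beta,
        fst=fst,
        n_pops=design.n_plots,
        seed=sub(),
    )
    gm, truth = simulate_genotypes(
        env, truth, n_neutral=n_neutral, missing_rate=missing_rate,
        populations=samples["site"].to_numpy(),
    )
    go_map = generate_go_map(gm.loci["gene_id"], seed=sub())
    return Fixture(dem, samples, env, gm, truth, go_map, stack)


def write_fixture(dir_path, fixture: Fixture) -> dict[str, Path]:
    """Write the fixture as the file set the pipeline readers consume."""
    d = Path(dir_path)
    try:
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "dem": d / "dem.tif",
            "dem_ascii": d / "dem.asc",
            "samples": d / "samples.tsv",
            "vcf": d / "genotypes.vcf",
            "dosages": d / "genotypes.tsv",
            "annotations": d / "annotations.tsv",
            "go_map": d / "go_map.tsv",
            "truth": d / "truth.tsv",
        }
        terrain.write_geotiff(fixture.dem, paths["dem"])
        terrain.write_ascii_grid(fixture.dem, paths["dem_ascii"])
        fixture.samples.to_csv(paths["samples"], sep="\t", index=False)
        genotype_io.write_vcf(fixture.genotypes, paths["vcf"])
        fixture.genotypes.to_tsv(paths["dosages"])
        fixture.genotypes.loci.to_csv(paths["annotations"], sep="\t", index=False, na_rep="NA")
        fixture.go_map.to_csv(paths["go_map"], sep="\t", index=False)
        fixture.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    except OSError as exc:
        raise IOError(f"cannot write fixture to {d}: {exc}") from exc
    return paths
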