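"""End-to-end orchestration of the multiscale GEA workflow.

A run takes a DEM, a sample table, genotypes and annotations; derives the
multiscale terrain stack; extracts and standardizes the environment
matrix; filters, imputes and partitions the genotypes; optionally
conditions on population-structure axes (regional mode); fits the eight
variable-set RDA models; scans for outlier loci; assigns them to driving
variables; tallies genes; and tests GO enrichment.  Everything flows from
one master seed recorded in the run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    association,
    enrichment,
    genotype_io,
    model_selection,
    ordination,
    outlier_scan,
    terrain,
)

logger = logging.getLogger("msgea")


@dataclass
class RunConfig:
    """Flat key=value configuration for a pipeline run."""

    dem: str = ""
    samples: str = ""
    genotypes: str = ""
    annotations: str = ""
    go_map: str = ""
    out_dir: str = "msgea_out"
    mode: str = "local"           # local | regional (conditions on structure PCs)
    seed: int = 0
    alpha_outlier: float = 0.01   # Bonferroni family-wise alpha
    alpha_select: float = 0.01    # forward-selection / permutation alpha
    n_perm: int = 1000
    maf_min: float = 0.025
    max_missing: float = 0.10
    ld_r2_max: float = 0.2
    ld_window: int = 50
    n_structure_pcs: int = 3
    spearman_threshold: float = 0.8
    forward_selection: bool = True
    base_resolution: float = 0.5
    resolutions: tuple = terrain.DEFAULT_RESOLUTIONS
    scan_radius: float = 100.0
    scan_directions: int = 16
    latitude: float = 46.3

    def terrain_params(self) -> terrain.TerrainParams:
        return terrain.TerrainParams(
            scan_radius=self.scan_radius,
            scan_directions=self.scan_directions,
            latitude=self.latitude,
        )


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    cfg = RunConfig()
    bools = {"true": True, "false": False, "yes": True, "no": False}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if not hasattr(cfg, key):
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            setattr(cfg, key, bools[val.lower()])
        elif isinstance(current, int):
            setattr(cfg, key, int(val))
        elif isinstance(current, float):
            setattr(cfg, key, float(val))
        elif isinstance(current, tuple):
            setattr(cfg, key, tuple(float(v) for v in val.split(",")))
        else:
            setattr(cfg, key, val)
    return cfg


@dataclass
class ModelReport:
    """One variable set's fitted model and scan results."""

    set_name: str
    n_predictors: int
    r2: float
    adj_r2: float
    k: int
    outliers: outlier_scan.OutlierTable
    ps: float
    assignments: pd.Series
    gene_table: pd.DataFrame
    enrichment: pd.DataFrame


@dataclass
class RunResult:
    reports: list[ModelReport]
    comparison: pd.DataFrame
    summary: pd.DataFrame
    k: int
    screen_flagged: list
    selection: model_selection.VariableSet | None
    partition: ordination.PartitionResult | None = None
    env: terrain.EnvironmentMatrix | None = None
    high_impact_ids: list = field(default_factory=list)


def _fit_and_scan(
    name: str,
    Yc: np.ndarray,
    X: pd.DataFrame,
    Z,
    k: int | None,
    loci: pd.DataFrame,
    high_ids: list[str],
    go_map: pd.DataFrame | None,
    cfg: RunConfig,
    seed: int,
) -> tuple[ModelReport, ordination.RdaModel]:
    model = ordination.rda(Yc, X, Z=Z)
    k_use = k if k is not None else ordination.select_k_scree(model.eigenvalues)
    k_use = min(k_use, model.n_axes)
    table = outlier_scan.scan_loadings(
        model.loadings, loci, k=k_use, alpha=cfg.alpha_outlier, seed=seed
    )
    ps = outlier_scan.compute_ps(table, high_ids) if high_ids else float("nan")
    out_idx = np.where(table.table["outlier"].to_numpy())[0]
    if out_idx.size:
        # species-score scaling: weight axes by sqrt(eigenvalue) so the
        # projection respects each axis's share of constrained variance
        weighted = model.loadings[:, :k_use] * np.sqrt(model.eigenvalues[:k_use])
        assignments = association.assign_variable(
            weighted, model.biplot_scores.iloc[:, :k_use], out_idx
        )
        table.table["assigned_variable"] = pd.Series(dtype=object)
        table.table.loc[out_idx, "assigned_variable"] = assignments.to_numpy()
        gene_table = association.gene_tally(
            assignments, table.table["gene_id"]
        )
    else:
        assignments = pd.Series(dtype=object, name="assigned_variable")
        table.table["assigned_variable"] = pd.Series(dtype=object)
        gene_table = pd.DataFrame(columns=["gene_id", "variable", "n_snps", "n_variables"])
    enr = pd.DataFrame()
    if go_map is not None and high_ids:
        hi_meta = loci.set_index("locus_id")
        universe = set(hi_meta.loc[high_ids, "gene_id"].dropna())
        hit_loci = [i for i in table.outlier_ids if i in high_ids]
        test_genes = set(hi_meta.loc[hit_loci, "gene_id"].dropna()) if hit_loci else set()
        enr = enrichment.fisher_enrichment(test_genes, universe, go_map)
    report = ModelReport(
        set_name=name,
        n_predictors=X.shape[1],
        r2=model.r2,
        adj_r2=model.adj_r2,
        k=k_use,
        outliers=table,
        ps=ps,
        assignments=assignments,
        gene_table=gene_table,
        enrichment=enr,
    )
    return report, model


def run_gea(
    env: terrain.EnvironmentMatrix,
    genotypes: genotype_io.GenotypeMatrix,
    cfg: RunConfig,
    go_map: pd.DataFrame | None = None,
    variable_sets: list[model_selection.VariableSet] | None = None,
    geography: pd.DataFrame | None = None,
) -> RunResult:
    """The analysis core, from an extracted environment matrix onward.

    ``env`` holds raw extracted values (standardized internally);
    ``genotypes`` is the unfiltered matrix with category annotations.
    """
    rng = np.random.default_rng(cfg.seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))

    envs = env if env.standardized else env.standardize()

    # collinearity screen among variable types at the base resolution (report only)
    base_cols = [
        c for c in envs.data.columns
        if terrain.parse_column(c)[1] == cfg.base_resolution
        and terrain.parse_column(c)[0] != "ELEV"
    ]
    flagged = []
    if len(base_cols) >= 2:
        _, _, flagged = ordination.spearman_screen(
            envs.data[base_cols], threshold=cfg.spearman_threshold
        )

    gm = genotype_io.filter_snps(genotypes, cfg.maf_min, cfg.max_missing)
    gm = genotype_io.impute_missing(gm, seed=sub())
    inter, intra, high_ids = genotype_io.partition_by_annotation(gm)

    Z = None
    partition = None
    if cfg.mode == "regional":
        pruned = genotype_io.ld_prune(inter, cfg.ld_r2_max, cfg.ld_window)
        k_pcs = min(cfg.n_structure_pcs, pruned.n_loci, pruned.n_samples - 1)
        scores, _, _ = ordination.pca(pruned.dosages, k_pcs)
        Z = pd.DataFrame(
            scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
        )
        if geography is not None:
            partition = ordination.variance_partition(
                intra.dosages, envs.data, Z, geography
            )

    Yc = intra.dosages - intra.dosages.mean(axis=0)
    loci = intra.loci

    sets = variable_sets or model_selection.build_variable_sets(
        envs, resolutions=cfg.resolutions, base_resolution=cfg.base_resolution
    )
    vs_all = next((s for s in sets if s.name == "VS-all"), sets[-1])
    model_all = ordination.rda(Yc, envs.data[vs_all.columns], Z=Z)
    k = ordination.select_k_scree(model_all.eigenvalues)
    # the Mahalanobis scan needs loci > 5K to estimate its scatter
    k = max(2, min(k, (Yc.shape[1] - 1) // 5))
    logger.info("retaining K=%d constrained axes (scree on %s)", k, vs_all.name)

    selection = None
    if cfg.forward_selection:
        try:
            selection = model_selection.forward_select(
                Yc,
                terrain.EnvironmentMatrix(envs.data[vs_all.columns], standardized=True),
                alpha=cfg.alpha_select,
                n_perm=cfg.n_perm,
                seed=sub(),
            )
            if len(selection.columns) >= 1:
                sets = sets + [selection]
        except model_selection.SelectionError as exc:
            logger.warning("forward selection skipped: %s", exc)

    reports = []
    for vs in sets:
        seed_vs = sub()
        report, _ = _fit_and_scan(
            vs.name, Yc, envs.data[vs.columns], Z, k, loci, high_ids, go_map, cfg, seed_vs
        )
        reports.append(report)

    named = {r.set_name: set(r.outliers.outlier_ids) for r in reports}
    comparison = (
        outlier_scan.compare_outlier_sets(named) if len(named) >= 2 else pd.DataFrame()
    )
    summary = summarize_models(reports)
    return RunResult(
        reports=reports,
        comparison=comparison,
        summary=summary,
        k=k,
        screen_flagged=flagged,
        selection=selection,
        partition=partition,
        env=envs,
        high_impact_ids=high_ids,
    )


def summarize_models(reports: list[ModelReport]) -> pd.DataFrame:
    """Per-set comparison table: adjusted R^2 (raw and per input variable),
    p_S and outlier counts by category."""
    if not reports:
        raise ValueError("need at least one model report")
    rows = []
    for r in reports:
        tab = r.outliers.table
        out = tab[tab["outlier"]]
        rows.append(
            {
                "set": r.set_name,
                "n_predictors": r.n_predictors,
                "r2": r.r2,
                "adj_r2": r.adj_r2,
                "adj_r2_per_variable": r.adj_r2 / r.n_predictors if r.n_predictors else np.nan,
                "k": r.k,
                "ps": r.ps,
                "n_outliers": len(out),
                "n_outliers_high_impact": int((out["category"] == "high_impact").sum()),
            }
        )
    return pd.DataFrame(rows)


def run_site_analysis(cfg: RunConfig) -> RunResult:
    """File-based entry point: load inputs, run, write the report bundle."""
    for key in ("dem", "samples", "genotypes", "annotations"):
        if not getattr(cfg, key):
            raise ValueError(f"config is missing required input {key!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "terrain"
    try:
        dem = (
            terrain.read_geotiff(cfg.dem)
            if str(cfg.dem).endswith((".tif", ".tiff"))
            else terrain.read_ascii_grid(cfg.dem)
        )
        stack = terrain.derive_stack(
            dem, resolutions=cfg.resolutions, params=cfg.terrain_params()
        )
        stage = "extraction"
        samples = pd.read_csv(cfg.samples, sep="\t")
        env = terrain.extract_at_points(stack, samples)
        stage = "genotypes"
        fmt = "vcf" if str(cfg.genotypes).endswith(".vcf") else "tsv"
        gm = genotype_io.read_genotypes(cfg.genotypes, format=fmt)
        ann = genotype_io.read_annotations(cfg.annotations)
        gm = genotype_io.attach_annotations(gm, ann)
        go_map = enrichment.read_go_map(cfg.go_map) if cfg.go_map else None
        stage = "gea"
        geography = samples[["x", "y"]] if cfg.mode == "regional" else None
        result = run_gea(env, gm, cfg, go_map=go_map, geography=geography)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # report bundle
    result.summary.to_csv(out / "models_summary.tsv", sep="\t", index=False)
    for r in result.reports:
        r.outliers.to_tsv(out / f"outliers_{r.set_name}.tsv")
        if not r.gene_table.empty:
            r.gene_table.to_csv(out / f"genes_{r.set_name}.tsv", sep="\t", index=False)
        if not r.enrichment.empty:
            r.enrichment.to_csv(out / f"go_{r.set_name}.tsv", sep="\t", index=False)
    if not result.comparison.empty:
        result.comparison.to_csv(out / "outlier_set_comparison.tsv", sep="\t", index=False)
    if result.selection is not None and not result.selection.provenance.empty:
        result.selection.provenance.to_csv(out / "selection_trace.tsv", sep="\t", index=False)
    manifest = {
        **{k: str(v) for k, v in asdict(cfg).items()},
        "k_retained": str(result.k),
        "n_high_impact": str(len(result.high_impact_ids)),
        "screen_flagged": ";".join(f"{a}~{b}" for a, b, _ in result.screen_flagged),
    }
    (out / "run_manifest.txt").write_text(
        "\n".join(f"{k} = {v}" for k, v in manifest.items()) + "\n"
    )
    logger.info("report bundle written to %s", out)
    return result


def plot_model_comparison(summary: pd.DataFrame, path) -> None:
    """Simple two-panel comparison figure (adjusted R^2 per variable, p_S)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].bar(summary["set"], summary["adj_r2_per_variable"])
    axes[0].set_ylabel("adjusted R2 / n variables")
    axes[1].bar(summary["set"], summary["ps"])
    axes[1].set_ylabel("p_S")
    for ax in axes:
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
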