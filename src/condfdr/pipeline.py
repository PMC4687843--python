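"""End-to-end orchestration: GC -> conditional Q-Q -> cFDR -> clumping ->
annotation -> novelty -> optional expression validation, plus figure rendering.

Every run writes per-stage TSVs, a locus table shaped like the standard
"novel loci" report (locus number, lead SNP, gene, map location, nominal p,
unconditional FDR, minimal conditional FDR, Wald statistic, driving trait,
expression r), a resolved-config YAML and a machine-readable JSON manifest
with inputs, seeds, inflation estimates and per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .sumstats import read_sumstats, intersect_traits, AlignedPanel
from .gc import p_to_z, estimate_lambda_gc, apply_gc, GCEstimate
from .qq import conditional_qq, DEFAULT_THRESHOLDS, DEFAULT_FOCUS_MAX_LOGP
from .cfdr import (
    build_lookup,
    summarize,
    Lookup2D,
    DEFAULT_GRID_P1,
    DEFAULT_GRID_P2,
    DEFAULT_THRESHOLD,
)
from .clump import (
    read_ld,
    build_adjacency,
    greedy_lead_selection,
    assign_blocks,
    novelty_filter,
    DEFAULT_R2_CUT,
    Locus,
)
from .annotate import read_genes, annotate_loci
from .expression import ExpressionSet, validate_gene_set

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one pipeline run.

    All threshold defaults are the method's standard values: conditional FDR
    significance 0.01, Q-Q stratum ladder (0, 1, 2, 3) with display ceiling
    7.3, LD clumping r^2 cut 0.2, expression alpha 0.05.
    """

    primary: str = ""
    conditioners: dict = field(default_factory=dict)  # name -> path
    primary_name: str = "primary"
    ld: str | None = None
    genes: str | None = None
    known_rsids: list = field(default_factory=list)
    known_genes: list = field(default_factory=list)
    expression: str | None = None          # probes x samples TSV
    sample_sheet: str | None = None        # SAMPLE PHENO AGE BMI TSV
    probe_map: str | None = None           # PROBE GENE TSV
    outdir: str = "condfdr_run"
    seed: int = 0
    cfdr_threshold: float = DEFAULT_THRESHOLD
    qq_thresholds: tuple = DEFAULT_THRESHOLDS
    qq_focus_max_logp: float = DEFAULT_FOCUS_MAX_LOGP
    r2_cut: float = DEFAULT_R2_CUT
    expression_alpha: float = 0.05
    grid_p1_max: float = 10.0
    grid_p1_step: float = 0.1
    grid_p2_max: float = 10.0
    grid_p2_step: float = 0.5
    monotonize_lookup: bool = False
    raw_p_qq: bool = False
    probe_rule: str = "max_abs_r"
    figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=False)

    def grids(self):
        g1 = np.round(
            np.arange(0.0, self.grid_p1_max + 1e-9, self.grid_p1_step), 10
        )
        g2 = np.round(
            np.arange(0.0, self.grid_p2_max + 1e-9, self.grid_p2_step), 10
        )
        return g1, g2


@dataclass
class PipelineResult:
    panel: AlignedPanel
    gc_estimates: dict[str, GCEstimate]
    qq_curves: dict
    lookups: dict[str, Lookup2D]
    cfdr_table: pd.DataFrame
    loci: list[Locus]
    locus_table: pd.DataFrame
    expression_table: pd.DataFrame | None
    manifest: dict


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _gc_correct(table: pd.DataFrame, name: str, estimates: dict) -> pd.DataFrame:
    # GWAS p-values are two-sided: recover |z| via the p/2 quantile so that
    # median(z^2) matches the chi-square deviate used by apply_gc.
    z = p_to_z(table["p"].to_numpy(), table["direction"].to_numpy(), two_tailed=True)
    cats = table["category"].to_numpy()
    mask = cats == "intergenic"
    if mask.sum() == 0:
        logger.warning("trait %s: no intergenic SNPs; lambda_GC from all SNPs", name)
        gc = estimate_lambda_gc(z, None)
    else:
        gc = estimate_lambda_gc(z, mask)
    estimates[name] = gc
    out = table.copy()
    out["p"] = apply_gc(out["p"].to_numpy(), gc)
    return out


def write_lookup_tsv(lookup: Lookup2D, path) -> None:
    df = pd.DataFrame(
        lookup.fdr,
        index=pd.Index(lookup.grid_p1, name="neglog10_p1"),
        columns=[f"{b:g}" for b in lookup.grid_p2],
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(
    config: RunConfig,
    tables: dict[str, pd.DataFrame] | None = None,
    expression: ExpressionSet | None = None,
) -> PipelineResult:
    """Run every stage in order and write results under ``config.outdir``.

    ``tables`` may supply in-memory summary-statistic tables (internal
    schema; key ``config.primary_name`` plus one per conditioner), bypassing
    file reads — the synthetic generator and tests use this path.  Any stage
    error aborts the run with the stage named in the exception.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # --- read ---------------------------------------------------------
    info = stage("read")
    try:
        if tables is None:
            tables = {config.primary_name: read_sumstats(config.primary)}
            for name, path in config.conditioners.items():
                tables[name] = read_sumstats(path)
        cond_names = [n for n in tables if n != config.primary_name]
        info["n_snps_in"] = {n: int(len(t)) for n, t in tables.items()}
    except Exception as exc:
        raise RuntimeError(f"stage 'read' failed: {exc}") from exc

    # --- genomic control ---------------------------------------------
    info = stage("genomic_control")
    try:
        estimates: dict[str, GCEstimate] = {}
        corrected = {
            name: _gc_correct(tab, name, estimates) for name, tab in tables.items()
        }
        pd.DataFrame(
            [
                {
                    "trait": n,
                    "lambda_gc": e.lambda_gc,
                    "n_intergenic": e.n_intergenic,
                    "chi2_median_expected": e.chi2_median_expected,
                }
                for n, e in estimates.items()
            ]
        ).to_csv(out / "gc_estimates.tsv", sep="\t", index=False)
        info["lambda_gc"] = {n: e.lambda_gc for n, e in estimates.items()}
    except Exception as exc:
        raise RuntimeError(f"stage 'genomic_control' failed: {exc}") from exc

    # --- intersect ----------------------------------------------------
    info = stage("intersect")
    try:
        source = tables if config.raw_p_qq else corrected
        panel = intersect_traits(
            source[config.primary_name],
            {n: source[n] for n in cond_names},
            primary_name=config.primary_name,
        )
        panel.gc_applied = {n: not config.raw_p_qq for n in panel.trait_names}
        info["n_common_snps"] = panel.n_snps
    except Exception as exc:
        raise RuntimeError(f"stage 'intersect' failed: {exc}") from exc

    # --- conditional QQ ----------------------------------------------
    info = stage("conditional_qq")
    try:
        qq_curves = {}
        for name in cond_names:
            curves = conditional_qq(
                panel, name, config.qq_thresholds, config.qq_focus_max_logp
            )
            qq_curves[name] = curves
            for c in curves:
                pd.DataFrame(
                    c.points, columns=["neglog10_q", "neglog10_p"]
                ).to_csv(
                    out / f"qq_{name}_ge{c.stratum_threshold:g}.tsv",
                    sep="\t",
                    index=False,
                )
        info["strata_sizes"] = {
            n: [c.n_snps for c in cs] for n, cs in qq_curves.items()
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'conditional_qq' failed: {exc}") from exc

    # --- lookup build + cFDR assignment ------------------------------
    info = stage("cfdr")
    try:
        g1, g2 = config.grids()
        lookups = {
            name: build_lookup(
                panel.p_primary,
                panel.p_cond[name],
                g1,
                g2,
                trait=name,
                monotonize=config.monotonize_lookup,
            )
            for name in cond_names
        }
        for name, lk in lookups.items():
            write_lookup_tsv(lk, out / f"lookup_{name}.tsv")
        cfdr_table = summarize(panel, lookups, config.cfdr_threshold)
        cfdr_table.attrs["threshold"] = config.cfdr_threshold
        cfdr_table.to_csv(
            out / "cfdr_results.tsv", sep="\t", index=False, float_format="%.10g"
        )
        info["n_significant"] = int(cfdr_table["significant"].sum())
    except Exception as exc:
        raise RuntimeError(f"stage 'cfdr' failed: {exc}") from exc

    # --- clumping -----------------------------------------------------
    info = stage("clump")
    try:
        sig = cfdr_table[cfdr_table["significant"]]
        sig_map = dict(zip(sig["rsid"], sig["min_cfdr"]))
        p_map = dict(zip(sig["rsid"], sig["p_primary"]))
        driving = dict(zip(sig["rsid"], sig["driving_trait"]))
        chrom_of = dict(zip(cfdr_table["rsid"], cfdr_table["chrom"]))
        if config.ld:
            adj = read_ld(config.ld, chrom_of=chrom_of)
        else:
            adj = build_adjacency([])
        leads = greedy_lead_selection(sig_map, adj, config.r2_cut, p_map)
        snp_info = {
            r: (c, int(p))
            for r, c, p in zip(
                cfdr_table["rsid"], cfdr_table["chrom"], cfdr_table["pos"]
            )
        }
        loci = assign_blocks(
            leads, sig_map, adj, config.r2_cut, snp_info=snp_info, driving=driving
        )
        info["n_leads"] = len(leads)
        info["n_loci"] = len(loci)
    except Exception as exc:
        raise RuntimeError(f"stage 'clump' failed: {exc}") from exc

    # --- annotation + novelty ----------------------------------------
    info = stage("annotate")
    try:
        if config.genes:
            genes = read_genes(config.genes)
            loci = annotate_loci(loci, snp_info, genes)
        loci = novelty_filter(loci, set(config.known_rsids), set(config.known_genes))
        info["n_novel"] = sum(1 for l in loci if l.novelty == "novel")
        info["n_complex"] = sum(1 for l in loci if l.loc_class == "complex")
    except Exception as exc:
        raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc

    # --- expression validation (optional) ----------------------------
    info = stage("expression")
    expression_table = None
    try:
        if expression is None and config.expression:
            matrix = pd.read_csv(config.expression, sep="\t", index_col=0)
            samples = pd.read_csv(config.sample_sheet, sep="\t", index_col="SAMPLE")
            pmap = pd.read_csv(config.probe_map, sep="\t")
            expression = ExpressionSet(
                matrix=matrix,
                samples=samples.loc[matrix.columns],
                probe_to_gene=dict(zip(pmap["PROBE"], pmap["GENE"])),
            )
        if expression is not None:
            all_genes = sorted(set().union(*(l.genes for l in loci)) if loci else [])
            expression_table, summary = validate_gene_set(
                all_genes,
                expression,
                alpha=config.expression_alpha,
                probe_rule=config.probe_rule,
            )
            expression_table.to_csv(
                out / "expression_validation.tsv", sep="\t", index=False
            )
            info.update(_jsonable(summary))
    except Exception as exc:
        raise RuntimeError(f"stage 'expression' failed: {exc}") from exc

    # --- locus table --------------------------------------------------
    expr_r = {}
    if expression_table is not None:
        expr_r = dict(zip(expression_table["gene"], expression_table["r"]))
    lead_rows = cfdr_table.set_index("rsid")
    rows = []
    for locus in loci:
        lead = lead_rows.loc[locus.lead]
        sym = ",".join(sorted(locus.genes)) if locus.genes else "NA"
        r_vals = [expr_r.get(g) for g in sorted(locus.genes) if g in expr_r]
        rows.append(
            {
                "locus": locus.locus_id,
                "snp": locus.lead,
                "gene_symbol": sym,
                "map_loc": f"{lead['chrom']}:{int(lead['pos'])}",
                "p_primary": lead["p_primary"],
                "uncond_fdr": lead["uncond_fdr"],
                "min_cond_fdr": locus.min_cfdr,
                "wald_stat": float(
                    p_to_z(lead["p_primary"])
                    * (1 if lead.get("direction", 1) >= 0 else -1)
                ),
                "driving_trait": locus.driving_trait,
                "loc_class": locus.loc_class,
                "novelty": locus.novelty,
                "expression_r": r_vals[0] if r_vals else np.nan,
            }
        )
    locus_table = pd.DataFrame(
        rows,
        columns=[
            "locus", "snp", "gene_symbol", "map_loc", "p_primary", "uncond_fdr",
            "min_cond_fdr", "wald_stat", "driving_trait", "loc_class", "novelty",
            "expression_r",
        ],
    )
    locus_table.to_csv(out / "loci.tsv", sep="\t", index=False, float_format="%.10g")

    import condfdr

    manifest["version"] = condfdr.__version__
    manifest["inputs"] = {
        "primary": config.primary or "<in-memory>",
        "conditioners": list(cond_names),
        "ld": config.ld,
        "genes": config.genes,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)

    result = PipelineResult(
        panel=panel,
        gc_estimates=estimates,
        qq_curves=qq_curves,
        lookups=lookups,
        cfdr_table=cfdr_table,
        loci=loci,
        locus_table=locus_table,
        expression_table=expression_table,
        manifest=manifest,
    )
    if config.figures:
        render_figures(result, out)
    return result


# ----------------------------------------------------------------------
# figures
# ----------------------------------------------------------------------

def qq_figure(curves_by_trait: dict, path, focus_max_logp=DEFAULT_FOCUS_MAX_LOGP):
    """Conditional Q-Q figure: one curve per stratum, dotted null diagonal."""
    n = len(curves_by_trait)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(4 * max(n, 1), 4), squeeze=False)
    for ax, (trait, curves) in zip(axes[0], curves_by_trait.items()):
        for c in curves:
            if c.empty or len(c.points) == 0:
                continue
            ax.plot(
                c.points[:, 0], c.points[:, 1],
                label=f"-log10(p) >= {c.stratum_threshold:g}",
            )
        lim = focus_max_logp
        ax.plot([0, lim], [0, lim], "k:", label="null")
        ax.set_xlabel("empirical -log10(q)")
        ax.set_ylabel("nominal -log10(p)")
        ax.set_title(trait)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def manhattan_figure(cfdr_table: pd.DataFrame, leads: set[str], path,
                     threshold: float = DEFAULT_THRESHOLD):
    """Conditional-FDR Manhattan plot.

    y is -log10(min conditional FDR); SNPs below the FDR threshold are
    enlarged, and block leads get a black edge.
    """
    df = cfdr_table.copy()
    chrom_key = df["chrom"].map(
        lambda c: (0, int(c)) if str(c).isdigit() else (1, str(c))
    )
    df = df.iloc[np.argsort(chrom_key.to_numpy(), kind="mergesort")]
    offsets, xticks = {}, {}
    offset = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        offsets[chrom] = offset - grp["pos"].min()
        xticks[chrom] = offset + (grp["pos"].max() - grp["pos"].min()) / 2
        offset += grp["pos"].max() - grp["pos"].min() + 1
    x = df["pos"].to_numpy() + df["chrom"].map(offsets).to_numpy()
    y = -np.log10(df["min_cfdr"].to_numpy())
    sig = df["significant"].to_numpy()
    is_lead = df["rsid"].isin(leads).to_numpy()
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.scatter(x[~sig], y[~sig], s=3, c="0.6")
    ax.scatter(x[sig & ~is_lead], y[sig & ~is_lead], s=20, c="tab:blue")
    ax.scatter(
        x[is_lead], y[is_lead], s=40, c="tab:red", edgecolors="black", linewidths=0.8
    )
    ax.axhline(-np.log10(threshold), color="k", lw=0.5, ls="--")
    ax.set_xticks(list(xticks.values()), list(xticks.keys()), fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10(conditional FDR)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def lookup_heatmap(lookup: Lookup2D, path):
    """Heatmap of the 2-D lookup table; color encodes conditional FDR."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(
        lookup.grid_p2, lookup.grid_p1, -np.log10(lookup.fdr), shading="nearest"
    )
    fig.colorbar(im, ax=ax, label="-log10(conditional FDR)")
    ax.set_xlabel("-log10(p) conditioning trait")
    ax.set_ylabel("-log10(p) primary trait")
    ax.set_title(lookup.trait)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_figures(result: PipelineResult, outdir) -> list[Path]:
    """Render the Q-Q, Manhattan and lookup-heatmap figures for a run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out / "qq.png"
    qq_figure(result.qq_curves, p)
    paths.append(p)
    p = out / "manhattan.png"
    manhattan_figure(
        result.cfdr_table, {l.lead for l in result.loci}, p,
        threshold=float(result.cfdr_table.attrs.get("threshold", DEFAULT_THRESHOLD)),
    )
    paths.append(p)
    for name, lk in result.lookups.items():
        p = out / f"lookup_{name}.png"
        lookup_heatmap(lk, p)
        paths.append(p)
    return paths
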