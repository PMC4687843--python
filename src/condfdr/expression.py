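"""Covariate-adjusted expression-phenotype correlation for locus validation.

Candidate genes from the association analysis are validated against a bone
transcriptome: log2 probe intensities are correlated with the phenotype
(e.g. BMD in g/cm^2) after adjusting both for age and BMI.  The adjustment
residualizes both variables on an intercept plus the covariates; the
reported r is the Pearson correlation of the residuals (a partial
correlation) and its p-value uses a t-distribution with n - 2 - k degrees
of freedom (k covariates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ExpressionSet:
    """log2 probe x sample expression with per-sample phenotype and covariates.

    ``matrix`` is probes x samples; ``samples`` is indexed by sample id with
    columns PHENO, AGE, BMI; ``probe_to_gene`` maps probe id -> gene symbol.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValueError("matrix columns must match sample sheet order")
        if self.samples[["PHENO", "AGE", "BMI"]].isna().any().any():
            raise ValueError("missing phenotype/covariate values")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    def covariates(self) -> np.ndarray:
        return self.samples[["AGE", "BMI"]].to_numpy(dtype=float)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def adjusted_correlation(x, y, covariates):
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on an intercept plus the covariate
    columns; r is the Pearson correlation of the residuals and the two-sided
    p-value comes from t = r * sqrt(df / (1 - r^2)) with df = n - 2 - k.

    Raises on rank-deficient covariates; returns (nan, nan) with a warning
    when either residual has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != x.size:
        cov = cov.T
    n, k = cov.shape
    if x.size != n or y.size != n:
        raise ValueError("x, y and covariates must have matching sample counts")
    if n <= k + 4:
        raise ValueError(f"need more than {k + 4} samples for {k} covariates")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    # residuals at numerical-noise level mean the variable is an (exact)
    # linear function of the covariates
    if sx <= 1e-10 * max(np.linalg.norm(x), 1.0) or sy <= 1e-10 * max(
        np.linalg.norm(y), 1.0
    ):
        logger.warning("zero residual variance: correlation undefined")
        return float("nan"), float("nan")
    r = float((rx @ ry) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def validate_gene_set(
    genes: list[str],
    expr: ExpressionSet,
    alpha: float = 0.05,
    probe_rule: str = "max_abs_r",
) -> tuple[pd.DataFrame, dict]:
    """Expression-phenotype validation of a candidate gene list.

    For every submitted gene symbol, correlates its probe's log2 expression
    with the phenotype adjusted for age and BMI.  Genes without a probe are
    reported as undetected ("NA" row).  Genes with several probes use the
    probe with the largest |r| (``probe_rule="max_abs_r"``, default) or the
    first probe in matrix order (``"first"``).

    Returns a per-gene table (gene, probe, r, p, significant, detected) and
    a summary dict with both denominators: significant / detected and
    significant / submitted.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    gene_probes: dict[str, list[str]] = {}
    for probe, gene in expr.probe_to_gene.items():
        if probe in expr.matrix.index:
            gene_probes.setdefault(gene, []).append(probe)
    pheno = expr.samples["PHENO"].to_numpy(dtype=float)
    cov = expr.covariates()
    rows = []
    for gene in genes:
        probes = gene_probes.get(gene, [])
        if not probes:
            rows.append((gene, "NA", np.nan, np.nan, False, False))
            continue
        results = []
        for probe in probes:
            r, p = adjusted_correlation(
                expr.matrix.loc[probe].to_numpy(dtype=float), pheno, cov
            )
            results.append((probe, r, p))
        if probe_rule == "max_abs_r":
            if len(results) > 1:
                logger.info(
                    "gene %s has %d probes; keeping max |r|", gene, len(results)
                )
            probe, r, p = max(
                results, key=lambda t: -1.0 if np.isnan(t[1]) else abs(t[1])
            )
        elif probe_rule == "first":
            probe, r, p = results[0]
        else:
            raise ValueError(f"unknown probe_rule '{probe_rule}'")
        sig = bool(np.isfinite(p) and p < alpha)
        rows.append((gene, probe, r, p, sig, True))
    table = pd.DataFrame(
        rows, columns=["gene", "probe", "r", "p", "significant", "detected"]
    )
    n_detected = int(table["detected"].sum())
    n_sig = int(table["significant"].sum())
    summary = {
        "n_submitted": len(genes),
        "n_detected": n_detected,
        "n_significant": n_sig,
        "frac_of_detected": n_sig / n_detected if n_detected else float("nan"),
        "frac_of_submitted": n_sig / len(genes) if genes else float("nan"),
    }
    return table, summary
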