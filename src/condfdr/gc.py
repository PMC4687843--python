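"""Genomic control: p/z conversions and the intergenic-SNP inflation correction.

Population stratification and cryptic relatedness inflate GWAS test
statistics genome-wide.  The inflation factor lambda_GC is estimated from
intergenic SNPs — a category depleted of true association — as the median
squared z-score divided by the median of a chi-square distribution with one
degree of freedom; all test statistics are then divided by lambda_GC.

The p <-> z transform is one-tailed: |z| = Phi^-1(1 - p), signed by the
reported direction of effect (positive when the direction is unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import P_FLOOR

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GCEstimate:
    """Genomic inflation factor and the provenance of its estimate."""

    lambda_gc: float
    n_intergenic: int
    chi2_median_expected: float

    def __post_init__(self) -> None:
        if not self.lambda_gc > 0:
            raise ValueError("lambda_gc must be positive")


def p_to_z(p, direction=None, two_tailed: bool = False):
    """Inverse-normal transform of p-values to signed z-scores.

    By default the transform is one-tailed — the magnitude is the upper-tail
    standard-normal quantile of ``p`` — which is the "Wald statistic"
    convention used when reporting z-scores transformed from published
    p-values.  With ``two_tailed=True`` the magnitude is the quantile of
    ``p/2``, recovering |z| from a standard two-sided GWAS p-value (this is
    the convention consistent with the chi-square deviate used by
    :func:`apply_gc`).  The sign is taken from ``direction`` (+1, -1, or
    0/None for unknown -> positive).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = stats.norm.isf(p / 2 if two_tailed else p)
    if direction is not None:
        d = np.asarray(direction, dtype=float)
        sign = np.where(d < 0, -1.0, 1.0)
        z = z * sign
    if z.ndim == 0:
        return float(z)
    return z


def z_to_p(z, two_tailed: bool = False):
    """p-value of ``z`` (inverse of the unsigned :func:`p_to_z`).

    One-sided upper tail of ``z`` by default (exact inverse of the
    one-tailed quantile for any p in (0, 1]); two-sided p of the magnitude
    with ``two_tailed=True``.  Direction-signed z-scores must have the sign
    stripped before inversion — the sign carries the effect direction, not
    probability mass.
    """
    z = np.asarray(z, dtype=float)
    if two_tailed:
        p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    else:
        p = stats.norm.sf(z)
    if p.ndim == 0:
        return float(p)
    return p


def chi2_median() -> float:
    """Median of the chi-square distribution with one degree of freedom."""
    return float(stats.chi2.ppf(0.5, df=1))


def estimate_lambda_gc(
    z,
    intergenic_mask=None,
    min_snps: int = 1000,
) -> GCEstimate:
    """Estimate the genomic inflation factor from (intergenic) z-scores.

    lambda_GC = median(z^2 over masked SNPs) / median of chi-square(1 df).

    When ``intergenic_mask`` is None, all SNPs are used with a prominent
    warning (the estimate is then biased upward by true associations).
    Fewer than ``min_snps`` masked SNPs triggers a warning; an empty mask or
    an all-zero z vector is an error.
    """
    z = np.asarray(z, dtype=float)
    if intergenic_mask is None:
        logger.warning(
            "no intergenic annotation available: estimating lambda_GC from ALL "
            "%d SNPs; the estimate may be inflated by true associations", len(z)
        )
        masked = z
    else:
        mask = np.asarray(intergenic_mask, dtype=bool)
        if mask.shape != z.shape:
            raise ValueError("intergenic_mask must match z in shape")
        masked = z[mask]
    if masked.size == 0:
        raise ValueError("no SNPs selected for lambda_GC estimation")
    if masked.size < min_snps:
        logger.warning(
            "only %d SNPs used for lambda_GC (fewer than %d): estimate is noisy",
            masked.size, min_snps,
        )
    med = float(np.median(masked**2))
    if med == 0.0:
        raise ValueError("median squared z-score is zero; degenerate lambda_GC")
    lam = med / chi2_median()
    if lam < 1:
        logger.warning("lambda_GC = %.4f < 1 (deflation); applied as-is", lam)
    return GCEstimate(
        lambda_gc=lam, n_intergenic=int(masked.size),
        chi2_median_expected=chi2_median(),
    )


def apply_gc(p, gc: GCEstimate):
    """Divide the chi-square test statistics behind ``p`` by lambda_GC.

    Each p-value is converted to its 1-df chi-square deviate, divided by
    lambda_GC, and mapped back through the chi-square upper tail.  Deflation
    (lambda < 1) is applied as-is; results are floored at the global p floor.
    For lambda > 1 the map is monotone, so SNP ranks are unchanged.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2_dev = stats.chi2.isf(p, df=1)
    corrected = stats.chi2.sf(chi2_dev / gc.lambda_gc, df=1)
    corrected = np.minimum(np.maximum(corrected, P_FLOOR), 1.0)
    if corrected.ndim == 0:
        return float(corrected)
    return corrected
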