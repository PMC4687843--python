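"""Conditional (stratified) Q-Q curves for cross-trait enrichment.

The primary trait's p-values are plotted as nominal -log10(p) (y) against
empirical quantiles -log10(q) (x), where q = 1 - cdf(p) is the empirical
upper-tail quantile, within nested strata defined by conditioning-trait
significance (-log10 p2 >= 0, 1, 2, 3 by default).  If small primary-trait
p-values are enriched among SNPs that associate with the conditioning trait,
the curves shift leftward (earlier departure from the null diagonal) with
increasing stratum stringency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sumstats import AlignedPanel

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.0, 1.0, 2.0, 3.0)

#: Display ceiling: points with -log10 p at or above this (p <= 5e-8 region)
#: are excluded from the curve so the sub-genome-wide-significant behaviour
#: is in focus.
DEFAULT_FOCUS_MAX_LOGP = 7.3


@dataclass
class QQCurve:
    """One stratum's Q-Q curve.

    ``points`` is an (m, 2) array of (-log10 q, -log10 p) pairs ordered by
    increasing -log10 p; both coordinates are nondecreasing along the curve.
    ``n_snps`` is the full stratum size (before the display-ceiling cut).
    """

    stratum_threshold: float
    points: np.ndarray
    n_snps: int

    @property
    def empty(self) -> bool:
        return self.n_snps == 0


def stratify(panel: AlignedPanel, trait: str, thresholds=DEFAULT_THRESHOLDS):
    """Nested SNP index sets: stratum t = {i : -log10 p2_i >= t}.

    ``thresholds`` must be nondecreasing; strata smaller than 100 SNPs are
    flagged with a warning but still returned.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be nondecreasing")
    if trait not in panel.p_cond:
        raise KeyError(f"trait '{trait}' not in panel")
    neglog_p2 = -np.log10(panel.p_cond[trait])
    strata = []
    for t in thresholds:
        idx = np.flatnonzero(neglog_p2 >= t)
        if idx.size < 100:
            logger.warning(
                "stratum -log10(p) >= %g for %s has only %d SNPs", t, trait, idx.size
            )
        strata.append(idx)
    return strata


def qq_curve(p, focus_max_logp: float = DEFAULT_FOCUS_MAX_LOGP) -> QQCurve:
    """Empirical Q-Q curve of one stratum's p-values against the uniform null.

    For the i-th order statistic p_(i) (ascending), the empirical quantile is
    q = i/n (right-continuous ECDF, so q = 1 - cdf(p) stays in (0, 1]).
    Points with -log10 p >= ``focus_max_logp`` are excluded from the returned
    curve (display only; they still count toward n).
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        logger.warning("empty stratum: returning empty Q-Q curve")
        return QQCurve(stratum_threshold=np.nan, points=np.empty((0, 2)), n_snps=0)
    p_sorted = np.sort(p)
    q = np.arange(1, n + 1) / n
    neglog_p = -np.log10(p_sorted)
    neglog_q = -np.log10(q)
    keep = neglog_p < focus_max_logp
    # order by increasing -log10 p (largest p first)
    pts = np.column_stack([neglog_q[keep], neglog_p[keep]])[::-1]
    return QQCurve(stratum_threshold=np.nan, points=pts, n_snps=n)


def conditional_qq(
    panel: AlignedPanel,
    trait: str,
    thresholds=DEFAULT_THRESHOLDS,
    focus_max_logp: float = DEFAULT_FOCUS_MAX_LOGP,
):
    """Q-Q curves of the primary trait within each conditioning stratum."""
    strata = stratify(panel, trait, thresholds)
    curves = []
    for t, idx in zip(thresholds, strata):
        c = qq_curve(panel.p_primary[idx], focus_max_logp=focus_max_logp)
        c.stratum_threshold = float(t)
        curves.append(c)
    return curves
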