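"""Conditional false discovery rate estimation from two traits' p-values.

For a SNP with primary-trait p-value P1 and conditioning-trait p-value P2,
the conditional FDR is the posterior probability that the SNP is null for the
primary trait given that both p-values are at least as small as observed:

    FDR(P1 | P2) = pi0(P2) * P1 / F(P1 | P2)

where F(P1 | P2) is the conditional cdf of P1 given P2 <= p2 and pi0(P2) the
conditional null proportion.  The estimator here is deliberately
conservative: pi0 is fixed at 1 and F is replaced by the empirical
conditional cdf.  Per-SNP values are assigned by bilinear interpolation of
-log10(FDR) into a 2-D lookup table over (-log10 P1, -log10 P2); the
unconditional FDR is the degenerate case P2 <= 1 (all SNPs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .sumstats import AlignedPanel

logger = logging.getLogger(__name__)

DEFAULT_GRID_P1 = np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)
DEFAULT_GRID_P2 = np.round(np.arange(0.0, 10.0 + 1e-9, 0.5), 10)
DEFAULT_THRESHOLD = 0.01


@dataclass
class Lookup2D:
    """2-D conditional-FDR lookup table.

    ``grid_p1`` / ``grid_p2`` are -log10 p breakpoints; ``fdr[i, j]`` is the
    pointwise conditional-FDR estimate at (p1 = 10^-grid_p1[i],
    p2 = 10^-grid_p2[j]); ``n_at_node[j]`` is the size of the conditioning
    slice {P2 <= 10^-grid_p2[j]}.  Empty slices hold FDR 1 (maximally
    conservative).
    """

    grid_p1: np.ndarray
    grid_p2: np.ndarray
    fdr: np.ndarray
    n_at_node: np.ndarray
    trait: str = ""
    monotonized: bool = False
    _interp: RegularGridInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                (self.grid_p1, self.grid_p2),
                -np.log10(self.fdr),
                method="linear",
                bounds_error=False,
                fill_value=None,
            )
        return self._interp


def conditional_cdf(p1: float, p2: float, p_primary, p_cond) -> float:
    """Empirical conditional cdf F(P1 <= p1 | P2 <= p2) on a panel.

    Counts use inclusive (<=) comparisons.  Returns NaN ("no data in slice")
    when no SNP has P2 <= p2.
    """
    p_primary = np.asarray(p_primary, dtype=float)
    p_cond = np.asarray(p_cond, dtype=float)
    in_slice = p_cond <= p2
    denom = int(np.count_nonzero(in_slice))
    if denom == 0:
        return float("nan")
    num = int(np.count_nonzero(p_primary[in_slice] <= p1))
    return num / denom


def cfdr_point(p1: float, p2: float, p_primary, p_cond) -> float:
    """Pointwise conditional-FDR estimate min(1, p1 / F_hat(p1 | p2)).

    With pi0 fixed at 1 the estimate is conservative; an empty conditioning
    slice (or an empty numerator) returns 1.
    """
    F = conditional_cdf(p1, p2, p_primary, p_cond)
    if not np.isfinite(F) or F == 0.0:
        return 1.0
    return min(1.0, p1 / F)


def uncond_fdr(p1: float, p_primary) -> float:
    """Unconditional FDR of the primary trait alone: the p2 = 1 degenerate case."""
    p_primary = np.asarray(p_primary, dtype=float)
    return cfdr_point(p1, 1.0, p_primary, np.ones_like(p_primary))


def uncond_fdr_vector(p_primary) -> np.ndarray:
    """Unconditional FDR evaluated at every SNP's own p-value (vectorized).

    Equivalent to calling :func:`uncond_fdr` per SNP: F_hat(p1) is the
    inclusive ECDF rank / n.
    """
    p = np.asarray(p_primary, dtype=float)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    # inclusive rank: number of values <= p_i
    ranks = np.searchsorted(sorted_p, p, side="right")
    F = ranks / p.size
    return np.minimum(1.0, p / F)


def build_lookup(
    p_primary,
    p_cond,
    grid_p1=DEFAULT_GRID_P1,
    grid_p2=DEFAULT_GRID_P2,
    trait: str = "",
    monotonize: bool = False,
) -> Lookup2D:
    """Evaluate the pointwise conditional-FDR estimator on a 2-D grid.

    Node (a, b) holds cfdr_point(10^-a, 10^-b); the computation shares the
    sorted conditioning slices across the p1 axis for speed but is exactly
    the pointwise estimator at every node.  ``monotonize`` applies a running
    minimum along increasing -log10 p1 at fixed p2 (off by default: the raw
    estimator is reported).
    """
    grid_p1 = np.asarray(grid_p1, dtype=float)
    grid_p2 = np.asarray(grid_p2, dtype=float)
    for g, name in ((grid_p1, "grid_p1"), (grid_p2, "grid_p2")):
        if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 nodes")
    p_primary = np.asarray(p_primary, dtype=float)
    p_cond = np.asarray(p_cond, dtype=float)

    p1_vals = 10.0 ** (-grid_p1)
    fdr = np.ones((grid_p1.size, grid_p2.size))
    n_at_node = np.zeros(grid_p2.size, dtype=int)
    for j, b in enumerate(grid_p2):
        in_slice = p_cond <= 10.0 ** (-b)
        n = int(np.count_nonzero(in_slice))
        n_at_node[j] = n
        if n == 0:
            continue  # FDR stays 1
        sorted_slice = np.sort(p_primary[in_slice])
        counts = np.searchsorted(sorted_slice, p1_vals, side="right")
        with np.errstate(divide="ignore", invalid="ignore"):
            col = np.where(counts > 0, p1_vals / (counts / n), 1.0)
        fdr[:, j] = np.minimum(1.0, col)
    if monotonize:
        fdr = np.minimum.accumulate(fdr, axis=0)
    return Lookup2D(
        grid_p1=grid_p1, grid_p2=grid_p2, fdr=fdr, n_at_node=n_at_node,
        trait=trait, monotonized=monotonize,
    )


def interpolate_fdr(lookup: Lookup2D, p1, p2):
    """Assign conditional FDR by bilinear interpolation into the lookup table.

    Interpolation is linear in -log10(FDR) over the (-log10 p1, -log10 p2)
    grid; queries beyond the grid are clamped to the boundary node.
    """
    a = -np.log10(np.asarray(p1, dtype=float))
    b = -np.log10(np.asarray(p2, dtype=float))
    scalar = a.ndim == 0 and b.ndim == 0
    a, b = np.broadcast_arrays(np.atleast_1d(a), np.atleast_1d(b))
    a = np.clip(a, lookup.grid_p1[0], lookup.grid_p1[-1])
    b = np.clip(b, lookup.grid_p2[0], lookup.grid_p2[-1])
    neglog = lookup.interpolator()(np.column_stack([a.ravel(), b.ravel()]))
    out = 10.0 ** (-neglog)
    out = np.minimum(out, 1.0).reshape(a.shape)
    if scalar:
        return float(out[0])
    return out


def summarize(
    panel: AlignedPanel,
    lookups: dict[str, Lookup2D],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-SNP conditional FDR across conditioning traits.

    Returns one row per panel SNP with the per-trait conditional FDR
    (``cfdr_<trait>``), the unconditional FDR of the primary trait alone,
    the minimum conditional FDR across traits, the trait attaining it
    ("driving" trait; ties broken by trait order in ``lookups``), and the
    significance call min_cfdr < ``threshold``.
    """
    traits = list(lookups)
    for t in traits:
        if t not in panel.p_cond:
            raise KeyError(f"lookup trait '{t}' not present in panel")
        if lookups[t].trait and lookups[t].trait != t:
            raise ValueError(
                f"lookup labelled '{lookups[t].trait}' supplied for trait '{t}'"
            )
    cfdr_mat = np.column_stack(
        [interpolate_fdr(lookups[t], panel.p_primary, panel.p_cond[t]) for t in traits]
    )
    argmin = np.argmin(cfdr_mat, axis=1)  # first minimum = config trait order
    min_cfdr = cfdr_mat[np.arange(len(cfdr_mat)), argmin]
    out = panel.snps.copy()
    out["p_primary"] = panel.p_primary
    for k, t in enumerate(traits):
        out[f"cfdr_{t}"] = cfdr_mat[:, k]
    out["uncond_fdr"] = uncond_fdr_vector(panel.p_primary)
    out["min_cfdr"] = min_cfdr
    out["driving_trait"] = [traits[k] for k in argmin]
    out["significant"] = min_cfdr < threshold
    n_tied = int(np.sum(np.sum(cfdr_mat == min_cfdr[:, None], axis=1) > 1))
    if n_tied:
        logger.info(
            "%d SNP(s) had tied minimal cFDR; ties broken by trait order %s",
            n_tied, traits,
        )
    return out
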