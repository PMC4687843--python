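"""Reading, validation and harmonization of per-trait GWAS summary statistics.

Summary-statistics files are whitespace/tab-separated tables with a header
row.  Column names vary across consortia, so the mapping from file columns to
the internal schema is explicit configuration with conventional defaults
(``SNP CHR BP P [DIR] [MAF] [CAT]``).  Internally each trait is a pandas
DataFrame with columns ``rsid, chrom, pos, p, direction, category, maf``;
p-values are floored at :data:`P_FLOOR` so that -log10 transforms stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Smallest representable p-value; zeros and smaller values are replaced by it.
P_FLOOR = 1e-300

#: Default file-column -> internal-field mapping.
DEFAULT_COLUMN_MAP = {
    "SNP": "rsid",
    "CHR": "chrom",
    "BP": "pos",
    "P": "p",
    "DIR": "direction",
    "MAF": "maf",
    "CAT": "category",
}

MANDATORY_FIELDS = ("rsid", "p")


class SumstatsError(ValueError):
    """Configuration or content error in a summary-statistics table."""


@dataclass
class AlignedPanel:
    """SNP-intersected matrix of p-values for a primary and conditioning traits.

    All vectors share the same length and SNP order (the primary table's
    order restricted to the common rsIDs).  ``p_cond`` maps each conditioning
    trait name to its p-value vector.
    """

    snps: pd.DataFrame  # columns rsid, chrom, pos (primary-trait coordinates)
    p_primary: np.ndarray
    p_cond: dict[str, np.ndarray]
    primary_name: str = "primary"
    gc_applied: dict[str, bool] = field(default_factory=dict)

    @property
    def trait_names(self) -> list[str]:
        return [self.primary_name] + list(self.p_cond)

    @property
    def n_snps(self) -> int:
        return len(self.p_primary)

    def __post_init__(self) -> None:
        n = len(self.snps)
        if len(self.p_primary) != n or any(len(v) != n for v in self.p_cond.values()):
            raise SumstatsError("panel vectors must all have the same length")


def _floor_p(p: np.ndarray) -> np.ndarray:
    n_floored = int(np.sum(p < P_FLOOR))
    if n_floored:
        logger.warning("floored %d p-value(s) below %.0e", n_floored, P_FLOOR)
    return np.maximum(p, P_FLOOR)


def read_sumstats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read one trait's summary statistics into the internal schema.

    Parameters
    ----------
    path : str or Path
        Whitespace- or tab-separated file with a header row.
    column_map : dict, optional
        Mapping of file column name -> internal field name.  Defaults to
        :data:`DEFAULT_COLUMN_MAP`.  Must name at least the SNP-id and
        p-value columns.

    Returns
    -------
    pandas.DataFrame with columns rsid, chrom, pos, p, direction, category,
    maf.  Rows with missing or non-numeric p are dropped (counted in the log);
    p is floored at :data:`P_FLOOR`.
    """
    df = pd.read_csv(path, sep=r"\s+")
    return from_frame(df, column_map=column_map, source=str(path))


def from_frame(
    df: pd.DataFrame,
    column_map: dict[str, str] | None = None,
    source: str = "<frame>",
) -> pd.DataFrame:
    """Normalize an in-memory table into the internal schema (see read_sumstats)."""
    path = source
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    present = {src: dst for src, dst in cmap.items() if src in df.columns}
    fields = set(present.values())
    for fld in MANDATORY_FIELDS:
        if fld not in fields:
            missing = [src for src, dst in cmap.items() if dst == fld]
            raise SumstatsError(
                f"mandatory column for field '{fld}' "
                f"(expected one of {missing}) not found in {path}"
            )
    out = df[list(present)].rename(columns=present)

    out["p"] = pd.to_numeric(out["p"], errors="coerce")
    n_bad = int(out["p"].isna().sum())
    if n_bad:
        logger.warning("%s: dropped %d row(s) with missing/non-numeric p", path, n_bad)
        out = out.dropna(subset=["p"])
    out = out.reset_index(drop=True)

    dup = out["rsid"].duplicated()
    if dup.any():
        first = out.loc[dup.idxmax(), "rsid"]
        raise SumstatsError(f"duplicate rsid in {path}: first duplicate is '{first}'")

    bad = (out["p"] < 0) | (out["p"] > 1)
    if bad.any():
        raise SumstatsError(f"{path}: {int(bad.sum())} p-value(s) outside [0, 1]")
    out["p"] = _floor_p(out["p"].to_numpy(dtype=float))

    for fld, default in (
        ("chrom", "NA"),
        ("pos", -1),
        ("direction", 0),
        ("category", "unknown"),
        ("maf", np.nan),
    ):
        if fld not in out.columns:
            out[fld] = default
    if out["direction"].dtype == object:
        out["direction"] = (
            out["direction"].map({"+": 1, "-": -1, "1": 1, "-1": -1}).fillna(0).astype(int)
        )
    out["chrom"] = out["chrom"].astype(str)
    return out[["rsid", "chrom", "pos", "p", "direction", "category", "maf"]]


def intersect_traits(
    primary: pd.DataFrame,
    conditioners: dict[str, pd.DataFrame],
    primary_name: str = "primary",
) -> AlignedPanel:
    """Restrict the primary and conditioning tables to their common rsIDs.

    The primary table's SNP order is preserved.  Raises
    :class:`SumstatsError` if the intersection across all traits is empty.
    """
    if not conditioners:
        raise SumstatsError("at least one conditioning trait is required")
    if len(primary) == 0 or any(len(t) == 0 for t in conditioners.values()):
        raise SumstatsError("all trait tables must be nonempty")

    common = set(primary["rsid"])
    for name, tab in conditioners.items():
        common &= set(tab["rsid"])
    if not common:
        raise SumstatsError("empty SNP intersection across traits")

    keep = primary[primary["rsid"].isin(common)].reset_index(drop=True)
    snps = keep[["rsid", "chrom", "pos"]].copy()
    p_cond = {}
    for name, tab in conditioners.items():
        aligned = tab.set_index("rsid").loc[keep["rsid"]]
        p_cond[name] = aligned["p"].to_numpy(dtype=float)
    logger.info(
        "intersected %d trait(s): %d common SNPs", 1 + len(conditioners), len(keep)
    )
    return AlignedPanel(
        snps=snps,
        p_primary=keep["p"].to_numpy(dtype=float),
        p_cond=p_cond,
        primary_name=primary_name,
    )


def write_panel(panel: AlignedPanel, path) -> None:
    """Write a panel to TSV with 17 significant digits (bit-exact round trip)."""
    df = panel.snps.copy()
    df[panel.primary_name] = panel.p_primary
    for name, vec in panel.p_cond.items():
        df[name] = vec
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_panel(path, primary_name: str | None = None) -> AlignedPanel:
    """Re-read a panel written by :func:`write_panel`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    trait_cols = [c for c in df.columns if c not in ("rsid", "chrom", "pos")]
    if primary_name is None:
        primary_name = trait_cols[0]
    cond = {c: df[c].to_numpy(dtype=float) for c in trait_cols if c != primary_name}
    return AlignedPanel(
        snps=df[["rsid", "chrom", "pos"]].copy(),
        p_primary=df[primary_name].to_numpy(dtype=float),
        p_cond=cond,
        primary_name=primary_name,
    )
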