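"""Nearest-gene annotation of SNPs and gene-based locus classification.

Each SNP is annotated with the closest gene by distance to the gene body
(distance 0 inside the body, otherwise the gap to the nearer edge; ties go
to the lexicographically smaller symbol).  A locus's gene set is the union
of its members' nearest genes; a locus annotating to more than one gene is
"complex", otherwise "single-gene".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def read_genes(path, bed_format: bool = False) -> pd.DataFrame:
    """Read a gene table (CHROM START END SYMBOL [STRAND], tab/space separated).

    Coordinates are 1-based inclusive internally; pass ``bed_format=True``
    for 0-based half-open input (start is shifted by +1).
    """
    df = pd.read_csv(path, sep=r"\s+")
    required = {"CHROM", "START", "END", "SYMBOL"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    genes = df.rename(
        columns={"CHROM": "chrom", "START": "start", "END": "end", "SYMBOL": "symbol"}
    )
    if bed_format:
        genes["start"] = genes["start"] + 1
    if "STRAND" in genes.columns:
        genes = genes.rename(columns={"STRAND": "strand"})
    else:
        genes["strand"] = "unknown"
    genes["chrom"] = genes["chrom"].astype(str)
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene with start > end")
    if (genes["symbol"].astype(str).str.len() == 0).any():
        raise ValueError("empty gene symbol")
    return genes[["chrom", "start", "end", "symbol", "strand"]].reset_index(drop=True)


def _distances(chrom: str, pos: int, genes: pd.DataFrame):
    sub = genes[genes["chrom"] == str(chrom)]
    if len(sub) == 0:
        return None, None
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    dist = np.maximum.reduce([start - pos, pos - end, np.zeros(len(sub), dtype=int)])
    return sub["symbol"].to_numpy(), dist


def nearest_gene(chrom: str, pos: int, genes: pd.DataFrame):
    """Closest gene to a position: (symbol, distance_bp), or ("NA", None).

    Distance is 0 when the position lies inside the gene body, else the gap
    to the nearer body edge.  Equidistant genes resolve to the
    lexicographically smaller symbol (logged).  Strand is ignored.
    """
    symbols, dist = _distances(chrom, pos, genes)
    if symbols is None:
        logger.warning("no genes on chromosome %s: annotation NA", chrom)
        return "NA", None
    dmin = dist.min()
    tied = symbols[dist == dmin]
    if len(tied) > 1:
        logger.info(
            "position %s:%d equidistant (%d bp) from genes %s; choosing %s",
            chrom, pos, dmin, sorted(tied), sorted(tied)[0],
        )
    return sorted(tied)[0], int(dmin)


def annotate_loci(loci, snp_coords: dict[str, tuple[str, int]], genes: pd.DataFrame):
    """Attach nearest-gene sets to loci and classify single-gene vs complex.

    ``snp_coords`` maps rsid -> (chrom, pos).  A locus's gene set is the
    union of members' nearest genes; when a SNP lies inside several
    overlapping gene bodies (all at distance 0), every such gene enters the
    set (this can make the locus complex; logged).  loc_class is "complex"
    iff the gene set has more than one symbol.
    """
    for locus in loci:
        symbols = set()
        for rsid in locus.members:
            chrom, pos = snp_coords[rsid]
            syms, dist = _distances(chrom, pos, genes)
            if syms is None:
                logger.warning("no genes on chromosome %s for %s", chrom, rsid)
                continue
            dmin = dist.min()
            if dmin == 0:
                inside = set(syms[dist == 0])
                if len(inside) > 1:
                    logger.info(
                        "%s lies inside %d overlapping genes: %s",
                        rsid, len(inside), sorted(inside),
                    )
                symbols |= inside
            else:
                symbols.add(sorted(syms[dist == dmin])[0])
        locus.genes = symbols
        locus.loc_class = "complex" if len(symbols) > 1 else "single-gene"
    return loci
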