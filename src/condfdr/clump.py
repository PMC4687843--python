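"""LD clumping of significant SNPs into independent loci.

Significant SNPs (conditional FDR below threshold) are clustered into LD
blocks at the r^2 > 0.2 level: SNPs are ranked by increasing conditional FDR
and a SNP is pruned when it is in LD (r^2 > cut) with any higher-ranked SNP.
The surviving SNPs are the block leads ("most significant SNP in each LD
block"); every pruned SNP joins the lead with which it has maximal r^2.
Loci are then triaged against a known-locus list: a block sharing an rsID or
a gene symbol with the reference study replicates it, otherwise it is novel.

LD is supplied as precomputed r^2 triplets from a reference panel; pairs
absent from the file are treated as unlinked (sparse LD files omit
sub-threshold pairs).  LD is intra-chromosomal: inter-chromosomal edges are
rejected when chromosome assignments are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_R2_CUT = 0.2


@dataclass
class Locus:
    """An independent LD block of significant SNPs."""

    locus_id: int
    lead: str
    members: set[str]
    min_cfdr: float
    driving_trait: str = ""
    genes: set[str] = field(default_factory=set)
    loc_class: str = ""  # "single-gene" | "complex", set by annotation
    novelty: str = ""    # "novel" | "replication", set by novelty_filter

    def __post_init__(self) -> None:
        if self.lead not in self.members:
            raise ValueError("lead SNP must be a member of its locus")


def read_ld(path, chrom_of: dict[str, str] | None = None) -> dict:
    """Read LD r^2 triplets (columns SNP_A SNP_B R2) into an adjacency dict.

    Each unordered pair is stored once per direction for O(1) lookup:
    ``adj[a][b] = r2``.  r^2 outside [0, 1] is an error; when ``chrom_of``
    is given, inter-chromosomal pairs are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+")
    required = {"SNP_A", "SNP_B", "R2"}
    if not required.issubset(df.columns):
        raise ValueError(f"LD file must have columns {sorted(required)}")
    return build_adjacency(
        df[["SNP_A", "SNP_B", "R2"]].itertuples(index=False, name=None), chrom_of
    )


def build_adjacency(edges, chrom_of: dict[str, str] | None = None) -> dict:
    """Build a symmetric adjacency dict from (rsid_a, rsid_b, r2) triples."""
    adj: dict[str, dict[str, float]] = {}
    for a, b, r2 in edges:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 for pair ({a}, {b}) outside [0, 1]: {r2}")
        if chrom_of is not None and a in chrom_of and b in chrom_of:
            if chrom_of[a] != chrom_of[b]:
                raise ValueError(
                    f"inter-chromosomal LD edge ({a}, {b}); LD is intra-chromosomal"
                )
        if a == b:
            continue
        adj.setdefault(a, {})[b] = r2
        adj.setdefault(b, {})[a] = r2
    return adj


def _rank_key(rsid, cfdr, p_nominal):
    p = p_nominal.get(rsid, 1.0) if p_nominal else 1.0
    return (cfdr[rsid], p, rsid)


def greedy_lead_selection(
    sig_snps: dict[str, float],
    adj: dict,
    r2_cut: float = DEFAULT_R2_CUT,
    p_nominal: dict[str, float] | None = None,
) -> list[str]:
    """Select block leads by greedy cFDR-ranked LD pruning.

    SNPs are visited in increasing conditional FDR (ties broken by smaller
    nominal p, then lexicographic rsid); a SNP becomes a lead unless it has
    r^2 strictly greater than ``r2_cut`` with an already-selected lead.
    Returned leads are pairwise r^2 <= r2_cut.
    """
    n_unlinked = sum(1 for s in sig_snps if s not in adj)
    if n_unlinked:
        logger.info(
            "%d of %d significant SNP(s) absent from the LD file; treated as "
            "unlinked (r2 = 0)", n_unlinked, len(sig_snps),
        )
    order = sorted(sig_snps, key=lambda s: _rank_key(s, sig_snps, p_nominal))
    leads: list[str] = []
    for snp in order:
        nbrs = adj.get(snp, {})
        if any(nbrs.get(lead, 0.0) > r2_cut for lead in leads):
            continue
        leads.append(snp)
    return leads


def assign_blocks(
    leads: list[str],
    sig_snps: dict[str, float],
    adj: dict,
    r2_cut: float = DEFAULT_R2_CUT,
    snp_info: dict[str, tuple[str, int]] | None = None,
    driving: dict[str, str] | None = None,
) -> list[Locus]:
    """Assign every significant SNP to a lead's block and number the loci.

    Non-lead SNPs join the lead with which they have maximal r^2 > r2_cut
    (the greedy pass guarantees at least one such lead exists).  Loci are
    numbered in genomic order of their lead (chromosome, position) when
    ``snp_info`` (rsid -> (chrom, pos)) is given, else by lead rank.
    """
    members: dict[str, set[str]] = {lead: {lead} for lead in leads}
    lead_set = set(leads)
    for snp in sig_snps:
        if snp in lead_set:
            continue
        nbrs = adj.get(snp, {})
        linked = [(nbrs[lead], lead) for lead in leads if nbrs.get(lead, 0.0) > r2_cut]
        if not linked:
            raise ValueError(
                f"significant SNP {snp} is not a lead and not linked to any lead"
            )
        _, best = max(linked, key=lambda t: (t[0], t[1]))
        members[best].add(snp)

    def chrom_sort_key(c: str):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    if snp_info is not None:
        ordered = sorted(
            leads, key=lambda s: (chrom_sort_key(snp_info[s][0]), snp_info[s][1])
        )
    else:
        ordered = list(leads)
    loci = []
    for i, lead in enumerate(ordered, start=1):
        loci.append(
            Locus(
                locus_id=i,
                lead=lead,
                members=members[lead],
                min_cfdr=min(sig_snps[m] for m in members[lead]),
                driving_trait=(driving or {}).get(lead, ""),
            )
        )
    return loci


@dataclass
class OverlapReport:
    """Cross-phenotype locus overlap: pairs sharing an rsID or gene symbol."""

    pairs: list[tuple[int, int]]  # (locus_id in A, locus_id in B)
    union_count: int


def overlap_loci(loci_a: list[Locus], loci_b: list[Locus]) -> OverlapReport:
    """Flag locus pairs as overlapping iff their rsID sets or gene sets intersect.

    The union count of distinct loci is the number of connected components of
    the bipartite overlap graph (overlapping loci collapse into one).
    """
    g = nx.Graph()
    g.add_nodes_from(("A", l.locus_id) for l in loci_a)
    g.add_nodes_from(("B", l.locus_id) for l in loci_b)
    pairs = []
    for la in loci_a:
        for lb in loci_b:
            if (la.members & lb.members) or (la.genes & lb.genes):
                pairs.append((la.locus_id, lb.locus_id))
                g.add_edge(("A", la.locus_id), ("B", lb.locus_id))
    return OverlapReport(pairs=pairs, union_count=nx.number_connected_components(g))


def novelty_filter(
    loci: list[Locus],
    known_rsids: set[str],
    known_genes: set[str],
) -> list[Locus]:
    """Mark each locus replication (shares a known rsID or gene) or novel."""
    for locus in loci:
        hit = bool(locus.members & set(known_rsids)) or bool(
            locus.genes & set(known_genes)
        )
        locus.novelty = "replication" if hit else "novel"
    return loci
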