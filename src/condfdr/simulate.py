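"""Seeded synthetic inputs with the statistical structure the method assumes.

Two-trait GWAS summary statistics are drawn from a four-component mixture:
null SNPs, SNPs affecting only trait 1 or only trait 2, and pleiotropic SNPs
affecting both.  Non-null SNPs receive Gaussian mean shifts on the z scale;
pleiotropic SNPs share a single standardized effect draw scaled by each
trait's effect SD, which induces the positive cross-trait dependence of
p-values that the conditional FDR leverages.  LD is compound-symmetric
within blocks: one shared latent factor per block with loading
sqrt(within_block_r) gives pairwise null z-correlation ~ within_block_r.
Genomic inflation multiplies z by sqrt(lambda) per trait.  The generator
also emits an expression set with planted phenotype correlations and a gene
map with a configurable "known locus" fraction, so every pipeline stage has
a ground-truthed input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionSet

COMPONENTS = ("null", "t1", "t2", "pleio")


@dataclass
class SimConfig:
    """Two-trait mixture simulation parameters.

    Defaults are the calibration conditions used throughout: 100,000 SNPs,
    95% null, 2% per-trait-specific, 1% pleiotropic, effect SD 3 on the z
    scale, no inflation and no LD.
    """

    n_snps: int = 100_000
    pi_null: float = 0.95
    pi_1: float = 0.02
    pi_2: float = 0.02
    pi_pleio: float = 0.01
    sigma1: float = 3.0
    sigma2: float = 3.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    ld_block_size: int = 1
    within_block_r: float = 0.0
    intergenic_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        pis = (self.pi_null, self.pi_1, self.pi_2, self.pi_pleio)
        if any(p < 0 for p in pis):
            raise ValueError("mixture proportions must be nonnegative")
        if abs(sum(pis) - 1.0) > 1e-12:
            raise ValueError("mixture proportions must sum to 1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("effect SDs must be positive")
        if not 0.0 <= self.within_block_r <= 0.99:
            raise ValueError("within_block_r must lie in [0, 0.99]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


def _positions(n: int, block_size: int, n_chrom: int = 22, spacing: int = 10_000):
    """Assign blocks to chromosomes round-robin; positions increase per chrom."""
    n_blocks = (n + block_size - 1) // block_size
    block_chrom = np.array([(b % n_chrom) + 1 for b in range(n_blocks)])
    chrom = np.repeat(block_chrom, block_size)[:n]
    pos = np.zeros(n, dtype=int)
    counter = dict.fromkeys(range(1, n_chrom + 1), 0)
    for i in range(n):
        counter[chrom[i]] += 1
        pos[i] = counter[chrom[i]] * spacing
    return chrom.astype(str), pos


def simulate_panel(config: SimConfig):
    """Draw two traits' summary statistics, LD triplets and truth labels.

    Returns ``(trait1, trait2, ld, truth)``: two summary-statistic tables
    (columns SNP CHR BP P DIR CAT), an LD triplet table (SNP_A SNP_B R2;
    pairs with theoretical r^2 > 0.05 only), and the per-SNP truth table
    (rsid, component, mu1, mu2).  Deterministic under a fixed seed.

    P is the standard two-sided GWAS p-value 2*Phi(-|z|) with the sign of z
    recorded in DIR: two-sided p-values are exactly uniform under the null,
    which is the distributional assumption both of the conditional-FDR
    estimator (whose numerator takes the null cdf of P1 to be the identity)
    and of the genomic-control chi-square deviate map.

    The intergenic category is planted on null SNPs only (with probability
    ``intergenic_frac``): the genomic-control estimator assumes intergenic
    SNPs are depleted of true association, and the generator realizes that
    assumption exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    comp = rng.choice(
        4, size=n, p=[config.pi_null, config.pi_1, config.pi_2, config.pi_pleio]
    )
    mu1 = np.zeros(n)
    mu2 = np.zeros(n)
    is_t1 = comp == 1
    is_t2 = comp == 2
    is_pl = comp == 3
    mu1[is_t1] = config.sigma1 * rng.standard_normal(is_t1.sum())
    mu2[is_t2] = config.sigma2 * rng.standard_normal(is_t2.sum())
    shared = rng.standard_normal(is_pl.sum())
    mu1[is_pl] = config.sigma1 * shared
    mu2[is_pl] = config.sigma2 * shared

    r = config.within_block_r
    bsize = config.ld_block_size
    n_blocks = (n + bsize - 1) // bsize
    block_of = np.repeat(np.arange(n_blocks), bsize)[:n]
    z = {}
    for trait, mu, lam in (("t1", mu1, config.lambda1), ("t2", mu2, config.lambda2)):
        factors = rng.standard_normal(n_blocks)[block_of]
        noise = np.sqrt(r) * factors + np.sqrt(1.0 - r) * rng.standard_normal(n)
        z[trait] = np.sqrt(lam) * (noise + mu)

    rsid = np.array([f"rs{i + 1}" for i in range(n)])
    chrom, pos = _positions(n, bsize)
    cat = np.full(n, "genic", dtype=object)
    null_idx = np.flatnonzero(comp == 0)
    inter = null_idx[rng.random(null_idx.size) < config.intergenic_frac]
    cat[inter] = "intergenic"

    tables = {}
    for trait in ("t1", "t2"):
        zt = z[trait]
        tables[trait] = pd.DataFrame(
            {
                "SNP": rsid,
                "CHR": chrom,
                "BP": pos,
                "P": np.maximum(2.0 * stats.norm.sf(np.abs(zt)), 1e-300),
                "DIR": np.where(zt < 0, -1, 1),
                "CAT": cat,
            }
        )

    ld_rows = []
    if bsize > 1 and r * r > 0.05:
        for b in range(n_blocks):
            idx = np.flatnonzero(block_of == b)
            for i, j in itertools.combinations(idx, 2):
                ld_rows.append((rsid[i], rsid[j], r * r))
    ld = pd.DataFrame(ld_rows, columns=["SNP_A", "SNP_B", "R2"])

    truth = pd.DataFrame(
        {
            "rsid": rsid,
            "component": np.array(COMPONENTS)[comp],
            "mu1": mu1,
            "mu2": mu2,
        }
    )
    return tables["t1"], tables["t2"], ld, truth


def simulate_expression(
    n_genes: int,
    n_samples: int = 84,
    planted_r=0.0,
    seed: int = 0,
    age_loading: float = 0.3,
    bmi_loading: float = 0.3,
    gene_symbols: list[str] | None = None,
) -> ExpressionSet:
    """Expression set with planted (partial) phenotype correlations.

    Phenotype, age and BMI are drawn independently; each gene's log2
    expression is planted_r * standardized-phenotype + sqrt(1 - r^2) * noise
    plus age/BMI contamination, so the age/BMI-adjusted partial correlation
    with the phenotype is planted_r.  The phenotype is on a BMD-like scale
    (mean 1.0 g/cm^2, SD 0.15); age ~ 65 +/- 8 y, BMI ~ 26 +/- 4 kg/m^2.
    """
    rng = np.random.default_rng(seed)
    r = np.broadcast_to(np.asarray(planted_r, dtype=float), (n_genes,)).copy()
    if np.any(np.abs(r) >= 1):
        raise ValueError("planted_r must lie in (-1, 1)")
    z_pheno = rng.standard_normal(n_samples)
    z_age = rng.standard_normal(n_samples)
    z_bmi = rng.standard_normal(n_samples)
    noise = rng.standard_normal((n_genes, n_samples))
    expr = (
        8.0
        + r[:, None] * z_pheno[None, :]
        + np.sqrt(1.0 - r[:, None] ** 2) * noise
        + age_loading * z_age[None, :]
        + bmi_loading * z_bmi[None, :]
    )
    if gene_symbols is None:
        gene_symbols = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    probes = [f"{i + 1:06d}_at" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    matrix = pd.DataFrame(expr, index=probes, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "PHENO": 1.0 + 0.15 * z_pheno,
            "AGE": 65.0 + 8.0 * z_age,
            "BMI": 26.0 + 4.0 * z_bmi,
        },
        index=pd.Index(sample_ids, name="SAMPLE"),
    )
    return ExpressionSet(
        matrix=matrix,
        samples=samples,
        probe_to_gene=dict(zip(probes, gene_symbols)),
    )


def simulate_genes(
    n_genes: int,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
    mean_length: int = 50_000,
) -> pd.DataFrame:
    """Non-overlapping gene intervals spread across chromosomes.

    Genes are laid out in disjoint slots per chromosome with jittered starts
    and lengths, guaranteeing pairwise-disjoint bodies.  Returns a table with
    columns chrom, start, end, symbol, strand (1-based inclusive).
    """
    if chrom_lengths is None:
        chrom_lengths = {str(c): 50_000_000 for c in range(1, 23)}
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    per_chrom = np.bincount(
        np.arange(n_genes) % len(chroms), minlength=len(chroms)
    )
    rows = []
    g = 0
    for ci, chrom in enumerate(chroms):
        k = per_chrom[ci]
        if k == 0:
            continue
        slot = chrom_lengths[chrom] // k
        for s in range(k):
            length = int(rng.integers(mean_length // 2, mean_length * 2))
            length = min(length, slot - 2)
            start = int(slot * s + 1 + rng.integers(0, max(1, slot - length - 1)))
            g += 1
            rows.append(
                (
                    chrom,
                    start,
                    start + length - 1,
                    f"GENE{g:04d}",
                    rng.choice(["+", "-"]),
                )
            )
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol", "strand"])
    genes["chrom"] = genes["chrom"].astype(str)
    return genes


def make_known_list(rsids, gene_symbols, fraction: float, seed: int = 0):
    """Sample a "known locus" list: a fraction of rsIDs and gene symbols.

    Emulates the primary study's reported loci for exercising novelty
    triage.  Returns (known_rsids, known_genes) as sets.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rsids = list(rsids)
    genes = list(gene_symbols)
    k_r = int(round(fraction * len(rsids)))
    k_g = int(round(fraction * len(genes)))
    known_r = set(rng.choice(rsids, size=k_r, replace=False)) if k_r else set()
    known_g = set(rng.choice(genes, size=k_g, replace=False)) if k_g else set()
    return known_r, known_g
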