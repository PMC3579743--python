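"""Synthetic SNP panels, haplotype pools and case-control cohorts.

Everything downstream (QC, relationship matrices, REML, coverage) is
exercised on data built here, with known allele frequencies, known LD
structure and known liability-scale heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._chromlen import ALL_CHROMOSOMES, CHROM_LENGTHS_BP

MISSING = np.int8(-1)

_NUCLEOTIDES = np.array(list("ACGT"))
_AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator from a seed, an existing Generator, or fresh entropy."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SnpPanel:
    """A panel of biallelic SNPs with reference-allele frequencies.

    ``p`` is the population frequency of ``allele_a`` (the counted allele).
    Positions are 1-based and strictly increasing within a chromosome.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        self.p = np.asarray(self.p, dtype=float)
        n = len(self.snp_id)
        for name in ("chromosome", "position", "allele_a", "allele_b", "p"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"panel field {name!r} has inconsistent length")
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if np.any(self.allele_a == self.allele_b):
            raise ValueError("the two alleles of a SNP must differ")
        for chrom in np.unique(self.chromosome.astype(str)):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing on chromosome {chrom}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def subset(self, index: np.ndarray) -> "SnpPanel":
        index = np.asarray(index)
        return SnpPanel(
            self.snp_id[index],
            self.chromosome[index],
            self.position[index],
            self.allele_a[index],
            self.allele_b[index],
            self.p[index],
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position": self.position,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
                "p": self.p,
            }
        )


@dataclass
class Cohort:
    """Unrelated individuals with allele-count genotypes over a SnpPanel.

    ``genotypes`` counts copies of ``allele_a`` in {0, 1, 2}; -1 is missing.
    ``phenotype`` is 1 for cases, 0 for controls, -9 for unknown. ``sex``
    follows the PLINK convention (1 male, 2 female, 0 unknown).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    sex: np.ndarray
    family_id: np.ndarray
    individual_id: np.ndarray
    liability: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.family_id = np.asarray(self.family_id, dtype=object)
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        n = self.genotypes.shape[0]
        for name in ("phenotype", "sex", "family_id", "individual_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"cohort field {name!r} has inconsistent length")
        valid = np.isin(self.genotypes, [-1, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotypes must be allele counts in {0,1,2} or -1")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def missing_rate(self) -> float:
        return float(np.mean(self.genotypes == MISSING))

    def allele_frequencies(self) -> np.ndarray:
        """Empirical frequency of allele_a per SNP among non-missing calls."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        return np.asarray(g.mean(axis=0) / 2.0)

    def subset(self, individuals=None, snps=None) -> "Cohort":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        liab = None if self.liability is None else self.liability[ind]
        return Cohort(
            self.genotypes[np.ix_(ind, snp)],
            self.phenotype[ind],
            self.sex[ind],
            self.family_id[ind],
            self.individual_id[ind],
            liability=liab,
        )


def concat_cohorts(cohorts: list[Cohort]) -> Cohort:
    """Stack cohorts that share a SNP panel (column order must match)."""
    n_snps = {c.n_snps for c in cohorts}
    if len(n_snps) != 1:
        raise ValueError("cohorts to concatenate must share a SNP panel")
    liab = None
    if all(c.liability is not None for c in cohorts):
        liab = np.concatenate([c.liability for c in cohorts])
    return Cohort(
        np.vstack([c.genotypes for c in cohorts]),
        np.concatenate([c.phenotype for c in cohorts]),
        np.concatenate([c.sex for c in cohorts]),
        np.concatenate([c.family_id for c in cohorts]),
        np.concatenate([c.individual_id for c in cohorts]),
        liability=liab,
    )


def _allocate_proportional(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items proportional to weights."""
    exact = n * weights / weights.sum()
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(exact - counts)[::-1]
        counts[order[:remainder]] += 1
    return counts


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:  # top up collisions; negligible for human-scale lengths
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n])


def simulate_panel(
    n_snps: int,
    maf_range: tuple[float, float] = (0.01, 0.99),
    chromosomes: list[str] | None = None,
    seed: int | np.random.Generator | None = None,
    include_ambiguous: bool = False,
) -> SnpPanel:
    """Simulate a biallelic SNP panel with Uniform(maf_range) frequencies.

    SNPs are assigned to chromosomes proportionally to physical length,
    mirroring liability variants scattered at random over the genome, and
    given strictly increasing positions. Allele pairs are drawn from the
    unambiguous pairs unless ``include_ambiguous`` is set (strand-ambiguous
    A/T and C/G pairs are only useful for exercising QC).
    """
    rng = as_rng(seed)
    if n_snps < 1:
        raise ValueError("n_snps must be at least 1")
    lo, hi = maf_range
    if not (0 < lo <= hi < 1):
        raise ValueError("maf_range must satisfy 0 < low <= high < 1")
    if chromosomes is None:
        chromosomes = ALL_CHROMOSOMES
    if len(chromosomes) == 0:
        raise ValueError("chromosome list must not be empty")
    unknown = set(map(str, chromosomes)) - set(CHROM_LENGTHS_BP)
    if unknown:
        raise ValueError(f"unknown chromosome labels: {sorted(unknown)}")

    lengths = np.array([CHROM_LENGTHS_BP[str(c)] for c in chromosomes], dtype=float)
    counts = _allocate_proportional(n_snps, lengths)

    chrom_col, pos_col = [], []
    for c, cnt, length in zip(chromosomes, counts, lengths):
        if cnt == 0:
            continue
        chrom_col.append(np.full(cnt, str(c), dtype=object))
        pos_col.append(_draw_positions(rng, cnt, int(length)))
    chrom_col = np.concatenate(chrom_col)
    pos_col = np.concatenate(pos_col)

    p = lo + (hi - lo) * rng.random(n_snps) if hi > lo else np.full(n_snps, lo)

    pairs = [
        (a, b)
        for a in "ACGT"
        for b in "ACGT"
        if a != b and (include_ambiguous or frozenset((a, b)) not in _AMBIGUOUS_PAIRS)
    ]
    pick = rng.integers(0, len(pairs), size=n_snps)
    allele_a = np.array([pairs[i][0] for i in pick], dtype=object)
    allele_b = np.array([pairs[i][1] for i in pick], dtype=object)

    snp_id = np.array([f"rs{i + 1}" for i in range(n_snps)], dtype=object)
    return SnpPanel(snp_id, chrom_col, pos_col, allele_a, allele_b, p)


def draw_genotypes(
    panel: SnpPanel, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw an (n, n_snps) allele-count matrix under Hardy-Weinberg."""
    rng = as_rng(seed)
    p32 = panel.p.astype(np.float32)
    g = (rng.random((n, panel.n_snps), dtype=np.float32) < p32).astype(np.int8)
    g += rng.random((n, panel.n_snps), dtype=np.float32) < p32
    return g


def inject_missingness(
    genotypes: np.ndarray, rate: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Return a copy with genotypes set missing independently at ``rate``."""
    rng = as_rng(seed)
    g = genotypes.copy()
    g[rng.random(g.shape) < rate] = MISSING
    return g


def truncated_upper_mean(threshold: float) -> float:
    """Mean of a standard normal conditioned on exceeding ``threshold``.

    This is the classical selection differential phi(t) / (1 - Phi(t)).
    """
    return float(stats.norm.pdf(threshold) / stats.norm.sf(threshold))


def simulate_case_control(
    panel: SnpPanel,
    effects,
    prevalence: float,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator | None = None,
    screen_controls: bool = False,
    chunk_size: int = 20_000,
    max_draws: int = 100_000_000,
) -> Cohort:
    """Sample unrelated cases and controls under the liability threshold model.

    Individuals are drawn from Hardy-Weinberg proportions at the panel's
    frequencies; liability is the additive genetic value from ``effects``
    plus a Normal(0, 1 - h2) environmental deviate. Cases are rejection
    samples whose liability exceeds the threshold for the given prevalence.
    Controls are a plain population draw unless ``screen_controls`` is set,
    in which case affected draws are rejected.
    """
    from .liability import assign_phenotype, liability_threshold

    rng = as_rng(seed)
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    if effects.n != panel.n_snps:
        raise ValueError("effect panel does not match the SNP panel")
    tau = liability_threshold(prevalence)

    need_cases, need_controls = n_cases, n_controls
    case_parts, control_parts = [], []
    case_liab, control_liab = [], []
    drawn = 0
    while need_cases > 0 or need_controls > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                "case/control rejection sampling exhausted its draw budget; "
                "is the requested prevalence attainable?"
            )
        g = draw_genotypes(panel, chunk_size, rng)
        drawn += chunk_size
        G = g.astype(np.float32) @ effects.a.astype(np.float32) - effects.mu_G
        _, y, affected = assign_phenotype(G, effects.h2, tau, rng)
        if need_cases > 0:
            idx = np.flatnonzero(affected)[:need_cases]
            case_parts.append(g[idx])
            case_liab.append(y[idx])
            need_cases -= len(idx)
        if need_controls > 0:
            keep = ~affected if screen_controls else np.ones(len(y), dtype=bool)
            idx = np.flatnonzero(keep)[:need_controls]
            control_parts.append(g[idx])
            control_liab.append(y[idx])
            need_controls -= len(idx)

    genotypes = np.vstack(case_parts + control_parts)
    liability = np.concatenate(case_liab + control_liab)
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    n = n_cases + n_controls
    # Sex is left unknown: every simulated genotype is diploid, including
    # chromosome X, so a nominal sex would contradict X heterozygosity and
    # trip the QC sex check. Tests of the sex check build hemizygous-style
    # X genotypes explicitly.
    sex = np.zeros(n, dtype=np.int8)
    fid = np.array([f"F{i + 1}" for i in range(n)], dtype=object)
    iid = np.array([f"I{i + 1}" for i in range(n)], dtype=object)
    return Cohort(genotypes, phenotype, sex, fid, iid, liability=liability)


@dataclass
class HaplotypePool:
    """Phased binary haplotypes arranged in linkage-disequilibrium blocks.

    A stand-in for reference-panel haplotypes in the coverage experiment:
    sites within a block are correlated (pairwise r-squared near
    ``target_r2``), sites in different blocks are independent.
    """

    haplotypes: np.ndarray  # (n_haplotypes, n_snps) in {0, 1}
    block: np.ndarray  # block index per SNP
    p: np.ndarray  # target allele frequency per SNP

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.block = np.asarray(self.block, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=float)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def simulate_haplotype_pool(
    n_haplotypes: int,
    n_blocks: int,
    block_size: int,
    target_r2: float = 0.7,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int | np.random.Generator | None = None,
) -> HaplotypePool:
    """Generate LD-blocked haplotypes by noisy copying of a block anchor.

    Each haplotype draws one anchor allele per block at the block's
    frequency; each site copies the anchor with probability c and is an
    independent Bernoulli draw otherwise. Two sites in the same block then
    have r-squared c**4, so c = target_r2 ** 0.25.
    """
    rng = as_rng(seed)
    if not 0 < target_r2 <= 1:
        raise ValueError("target_r2 must lie in (0, 1]")
    c = target_r2**0.25
    n_snps = n_blocks * block_size
    p_block = rng.uniform(*maf_range, size=n_blocks)
    p = np.repeat(p_block, block_size)
    block = np.repeat(np.arange(n_blocks), block_size)

    anchors = rng.random((n_haplotypes, n_blocks)) < p_block  # one per block
    site_anchor = np.repeat(anchors, block_size, axis=1)
    copy_mask = rng.random((n_haplotypes, n_snps)) < c
    fresh = rng.random((n_haplotypes, n_snps)) < p
    haps = np.where(copy_mask, site_anchor, fresh).astype(np.int8)

    freqs = haps.mean(axis=0)
    if np.any((freqs == 0) | (freqs == 1)):
        warnings.warn("monomorphic sites in simulated haplotype pool", stacklevel=2)
    return HaplotypePool(haps, block, p)
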