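"""Genomic coverage of a tag-SNP panel from haplotype linkage disequilibrium.

A genotyped SNP set ("forced tags", M of them) covers a region's common
variation to the extent that every common SNP is in LD (r-squared at least
X) with some tag. The number N of additional tags needed to complete the
cover measures the shortfall; M / (M + N) estimates coverage. Tag selection
is a set-cover problem: solved exactly by branch and bound when the
uncovered set is small, greedily otherwise (the two agree on the toy
regions used to validate the greedy rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import HaplotypePool, as_rng


@dataclass
class TagSet:
    indices: np.ndarray  # forced tags (the genotyped set)
    r2_threshold: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("forced tag indices must be unique")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("the r-squared threshold must lie in (0, 1]")


@dataclass
class CoverageEstimate:
    M: int  # forced tags
    N: int  # additional independent tags required
    r2_threshold: float
    region: int | str | None = None

    @property
    def coverage(self) -> float:
        return self.M / (self.M + self.N)


def pairwise_r2(haplotypes: np.ndarray, snps: np.ndarray | None = None) -> np.ndarray:
    """Squared Pearson correlation between SNP allele indicators.

    Computed across phased haplotypes, which equals the classical
    D^2 / (p(1-p) q(1-q)) haplotype-frequency form. Monomorphic SNPs have
    undefined r-squared; their rows/columns are NaN and a warning is issued.
    """
    h = np.asarray(haplotypes, dtype=float)
    if snps is not None:
        h = h[:, np.asarray(snps, dtype=int)]
    freq = h.mean(axis=0)
    mono = (freq == 0) | (freq == 1)
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs excluded from r2",
                      stacklevel=2)
    sd = h.std(axis=0)
    sd[mono] = np.nan
    z = (h - freq) / sd
    r = (z.T @ z) / h.shape[0]
    return r**2


def _min_extra_tags_exact(cover: np.ndarray, limit_nodes: int = 2_000_000) -> int:
    """Minimum number of columns of ``cover`` whose union is all rows.

    Branch and bound on set cover; ``cover[i, j]`` says candidate tag j
    covers SNP i. Feasibility is guaranteed because every SNP covers itself.
    """
    n_items = cover.shape[0]
    best = [n_items]
    masks = [int("".join("1" if b else "0" for b in cover[::-1, j]), 2)
             for j in range(cover.shape[1])]
    full = (1 << n_items) - 1
    order = np.argsort([-bin(m).count("1") for m in masks])
    masks = [masks[j] for j in order]
    nodes = [0]

    def recurse(uncovered: int, used: int) -> None:
        nodes[0] += 1
        if nodes[0] > limit_nodes:
            raise RuntimeError("exact set cover exceeded its node budget")
        if uncovered == 0:
            best[0] = min(best[0], used)
            return
        if used + 1 >= best[0]:
            return
        # branch on the lowest uncovered item: some chosen tag must cover it
        item = (uncovered & -uncovered)
        for m in masks:
            if m & item:
                recurse(uncovered & ~m, used + 1)

    recurse(full, 0)
    return best[0]


def _greedy_extra_tags(cover: np.ndarray) -> int:
    uncovered = np.ones(cover.shape[0], dtype=bool)
    n = 0
    while uncovered.any():
        gains = (cover & uncovered[:, None]).sum(axis=0)
        j = int(np.argmax(gains))  # first maximal gain wins ties
        uncovered &= ~cover[:, j]
        n += 1
    return n


def tag_cover(pool: HaplotypePool, forced_tags, candidates=None,
              r2_threshold: float = 0.5, exact_limit: int = 25,
              region: int | str | None = None) -> CoverageEstimate:
    """Coverage M / (M + N) of the forced tags at an r-squared threshold.

    ``candidates`` defaults to all pool SNPs with MAF > 0.1. N is the
    minimum number of candidate SNPs to add so every candidate reaches
    r-squared >= threshold with some tag (a tag covers itself); the minimum
    is exact below ``exact_limit`` uncovered SNPs, greedy above.
    """
    tags = forced_tags if isinstance(forced_tags, TagSet) else TagSet(forced_tags, r2_threshold)
    X = tags.r2_threshold
    freq = pool.frequencies()
    if candidates is None:
        candidates = np.flatnonzero(np.minimum(freq, 1 - freq) > 0.1)
    candidates = np.asarray(candidates, dtype=int)
    if len(candidates) == 0:
        raise ValueError("no candidate SNPs to cover")

    universe = np.union1d(candidates, tags.indices)
    r2 = pairwise_r2(pool.haplotypes, universe)
    pos = {snp: i for i, snp in enumerate(universe)}
    cand_rows = np.array([pos[s] for s in candidates])
    tag_rows = np.array([pos[s] for s in tags.indices])

    if len(tag_rows):
        covered = np.nanmax(r2[np.ix_(cand_rows, tag_rows)], axis=1) >= X
    else:
        covered = np.zeros(len(cand_rows), dtype=bool)
    uncovered_rows = cand_rows[~covered]
    if len(uncovered_rows) == 0:
        return CoverageEstimate(M=len(tags.indices), N=0,
                                r2_threshold=X, region=region)

    cover = r2[np.ix_(uncovered_rows, cand_rows)] >= X
    if len(uncovered_rows) <= exact_limit:
        N = _min_extra_tags_exact(cover)
    else:
        N = _greedy_extra_tags(cover)
    return CoverageEstimate(M=len(tags.indices), N=N, r2_threshold=X, region=region)


def coverage_curve(regions: list[HaplotypePool], forced_sets: list[np.ndarray],
                   fractions=(1.0, 0.5, 0.25, 0.125), reps: int = 5,
                   r2_thresholds=(0.5, 0.7, 0.9),
                   seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Coverage as the forced tag set is subsampled, per r-squared threshold.

    For each region, each subsampling fraction of the forced set is drawn
    ``reps`` times (once for fraction 1.0, which is deterministic) and
    coverage is computed at every threshold. Returns a tidy frame with one
    row per region x fraction x rep x threshold.
    """
    if len(regions) != len(forced_sets):
        raise ValueError("one forced tag set per region is required")
    rng = as_rng(seed)
    rows = []
    for region_id, (pool, forced) in enumerate(zip(regions, forced_sets)):
        forced = np.asarray(forced, dtype=int)
        for frac in fractions:
            n_draws = 1 if frac >= 1.0 else reps
            for rep in range(n_draws):
                k = max(1, int(round(frac * len(forced))))
                sub = (forced if frac >= 1.0
                       else rng.choice(forced, size=k, replace=False))
                for X in r2_thresholds:
                    est = tag_cover(pool, sub, r2_threshold=X, region=region_id)
                    rows.append({"region": region_id, "fraction": frac,
                                 "rep": rep, "r2_threshold": X, "M": est.M,
                                 "N": est.N, "coverage": est.coverage})
    return pd.DataFrame(rows)


def summarize_coverage(table: pd.DataFrame) -> pd.DataFrame:
    """Mean coverage per fraction x threshold, averaged over regions and reps."""
    return (table.groupby(["fraction", "r2_threshold"], sort=False)["coverage"]
            .mean().reset_index())
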