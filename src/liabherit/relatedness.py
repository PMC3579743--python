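"""Genetic relationship matrices, ancestry principal components, pruning.

The GRM follows the GCTA estimator: off-diagonal entries average
standardized genotype products over SNPs; diagonal entries use the
bias-adjusted form 1 + (x^2 - (1 + 2p)x + 2p^2) / (2p(1-p)). Allele
frequencies are estimated from the analyzed sample (cases and controls
jointly, so both groups share one scale) and missing genotypes are
mean-imputed, which makes per-chromosome GRMs combine exactly into the
pooled-SNP GRM.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panels import MISSING, Cohort, SnpPanel


@dataclass
class Grm:
    ids: list[tuple[str, str]]  # (family id, individual id)
    A: np.ndarray
    m: int  # contributing SNP count

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError("GRM shape does not match its id list")
        if self.m <= 0:
            raise ValueError("a GRM needs at least one contributing SNP")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class PcSet:
    vectors: np.ndarray  # individuals x k, orthonormal columns
    values: np.ndarray  # non-increasing

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def compute_grm(cohort: Cohort, panel: SnpPanel,
                chromosomes: list[str] | None = None) -> Grm:
    """GCTA-style GRM over the given chromosomes (all by default)."""
    if chromosomes is None:
        snp_idx = np.arange(panel.n_snps)
    else:
        wanted = set(map(str, chromosomes))
        snp_idx = np.flatnonzero(np.isin(panel.chromosome.astype(str), list(wanted)))
    if len(snp_idx) == 0:
        raise ValueError("no SNPs on the requested chromosomes")

    g = cohort.genotypes[:, snp_idx].astype(float)
    miss = g == MISSING
    g[miss] = np.nan
    p_hat = np.nanmean(g, axis=0) / 2.0
    if np.any(np.isnan(p_hat)) or np.any((p_hat <= 0) | (p_hat >= 1)):
        raise ValueError("monomorphic or all-missing SNP encountered; run QC first")

    g = np.where(miss, 2 * p_hat, g)  # mean imputation
    denom = 2 * p_hat * (1 - p_hat)
    z = (g - 2 * p_hat) / np.sqrt(denom)
    m = len(snp_idx)
    A = (z @ z.T) / m
    diag = 1.0 + np.mean((g**2 - (1 + 2 * p_hat) * g + 2 * p_hat**2) / denom, axis=1)
    np.fill_diagonal(A, diag)
    ids = list(zip(cohort.family_id, cohort.individual_id))
    return Grm(ids=ids, A=A, m=m)


def combine_grms(grms: list[Grm]) -> Grm:
    """SNP-count-weighted average of GRMs over the same individuals."""
    if len(grms) == 0:
        raise ValueError("no GRMs to combine")
    ids = grms[0].ids
    for g in grms[1:]:
        if g.ids != ids:
            raise ValueError("GRMs to combine must share an identical id list")
    m_total = sum(g.m for g in grms)
    A = sum(g.m * g.A for g in grms) / m_total
    return Grm(ids=ids, A=A, m=m_total)


def grm_pca(grm: Grm, k: int = 10) -> PcSet:
    """Top-k eigenpairs of the GRM (the ancestry covariates for REML)."""
    if k >= grm.n:
        raise ValueError("k must be smaller than the number of individuals")
    if not np.all(np.isfinite(grm.A)):
        raise ValueError("GRM contains non-finite entries")
    values, vectors = np.linalg.eigh(grm.A)
    order = np.argsort(values)[::-1][:k]
    vecs = vectors[:, order]
    # deterministic orientation: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, j]))
        if vecs[pivot, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PcSet(vectors=vecs, values=values[order])


def relatedness_prune(grm: Grm, cutoff: float = 0.05,
                      family_ids: np.ndarray | None = None,
                      call_rates: np.ndarray | None = None) -> np.ndarray:
    """Indices to keep so no cross-family pair exceeds the GRM cutoff.

    Greedy: repeatedly drop the individual involved in the most offending
    pairs; ties are broken toward the lower call rate when provided, then
    the higher index.
    """
    n = grm.n
    fams = (np.asarray(family_ids, dtype=object) if family_ids is not None
            else np.array([f for f, _ in grm.ids], dtype=object))
    off = np.triu(grm.A > cutoff, k=1)
    cross = fams[:, None] != fams[None, :]
    offending = off & cross
    alive = np.ones(n, dtype=bool)
    while True:
        active = offending & alive[:, None] & alive[None, :]
        counts = active.sum(axis=0) + active.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = counts.max()
        candidates = np.flatnonzero(counts == worst)
        if call_rates is not None and len(candidates) > 1:
            candidates = candidates[call_rates[candidates] == call_rates[candidates].min()]
        alive[candidates[-1]] = False
    return np.flatnonzero(alive)


# --- GCTA binary triplet I/O (grm.bin / grm.N.bin / grm.id) ---------------


def write_gcta_grm(grm: Grm, prefix: str | Path) -> None:
    """Write the GRM in GCTA's float32 lower-triangle binary convention."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    idx = np.tril_indices(grm.n)
    tri = grm.A[idx].astype(np.float32)
    tri.tofile(str(prefix) + ".grm.bin")
    np.full(len(tri), grm.m, dtype=np.float32).tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for fid, iid in grm.ids:
            fh.write(f"{fid}\t{iid}\n")


def read_gcta_grm(prefix: str | Path) -> Grm:
    prefix = str(prefix)
    ids = []
    with open(prefix + ".grm.id") as fh:
        for line in fh:
            fid, iid = line.split()
            ids.append((fid, iid))
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype=np.float32).astype(float)
    if len(tri) != n * (n + 1) // 2:
        raise ValueError("grm.bin size inconsistent with grm.id")
    A = np.zeros((n, n))
    idx = np.tril_indices(n)
    A[idx] = tri
    A = A + A.T - np.diag(np.diag(A))
    counts = np.fromfile(prefix + ".grm.N.bin", dtype=np.float32)
    m = int(round(float(counts[0]))) if len(counts) else 1
    return Grm(ids=ids, A=A, m=m)
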