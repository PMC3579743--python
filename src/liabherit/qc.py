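"""Quality-control filters for SNPs and individuals before heritability estimation.

The chain mirrors standard case-control GWAS practice: strand-ambiguous
SNPs out first, then individual call rate, sex concordance from X
heterozygosity, SNP call rate, minor allele frequency and Hardy-Weinberg
equilibrium. A report records, per rule, exactly what was removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .panels import MISSING, Cohort, SnpPanel

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class QcThresholds:
    snp_call_min: float = 0.98
    maf_min: float = 0.01
    hwe_p_min: float = 0.005
    ind_call_min: float = 0.98
    rel_max: float = 0.05
    male_het_max: float = 0.02  # X heterozygosity below -> inferred male
    female_het_min: float = 0.20  # above -> inferred female
    ancestry_call_min: float = 0.999
    ancestry_maf_min: float = 0.05
    ancestry_spacing_bp: int = 500_000
    hwe_method: str = "exact"  # or "chisq"


@dataclass
class QcReport:
    """Removal counts per rule plus the surviving index lists."""

    n_snps_in: int
    n_individuals_in: int
    removed_snps: dict[str, np.ndarray] = field(default_factory=dict)
    removed_individuals: dict[str, np.ndarray] = field(default_factory=dict)
    kept_snps: np.ndarray | None = None
    kept_individuals: np.ndarray | None = None

    @property
    def snp_counts(self) -> dict[str, int]:
        return {rule: len(idx) for rule, idx in self.removed_snps.items()}

    @property
    def individual_counts(self) -> dict[str, int]:
        return {rule: len(idx) for rule, idx in self.removed_individuals.items()}

    def check_partition(self) -> bool:
        """Removed and kept indices partition the input on both axes."""
        snp_removed = np.concatenate([*self.removed_snps.values(), np.array([], int)])
        ind_removed = np.concatenate([*self.removed_individuals.values(), np.array([], int)])
        snps_ok = (len(np.intersect1d(snp_removed, self.kept_snps)) == 0
                   and len(snp_removed) + len(self.kept_snps) == self.n_snps_in
                   and len(np.unique(snp_removed)) == len(snp_removed))
        inds_ok = (len(np.intersect1d(ind_removed, self.kept_individuals)) == 0
                   and len(ind_removed) + len(self.kept_individuals) == self.n_individuals_in
                   and len(np.unique(ind_removed)) == len(ind_removed))
        return bool(snps_ok and inds_ok)


def filter_ambiguous(panel: SnpPanel) -> np.ndarray:
    """Indices of SNPs whose allele pair is not strand-ambiguous (A/T, C/G)."""
    keep = []
    for i in range(panel.n_snps):
        a, b = str(panel.allele_a[i]).upper(), str(panel.allele_b[i]).upper()
        if a not in _COMPLEMENT or b not in _COMPLEMENT:
            raise ValueError(f"unknown allele code at SNP {panel.snp_id[i]}: {a}/{b}")
        if {a, b} not in _AMBIGUOUS:
            keep.append(i)
    return np.array(keep, dtype=int)


def hwe_test(n_hom_a: int, n_het: int, n_hom_b: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    The default is the conditional exact test (probabilities of all
    heterozygote counts compatible with the observed allele counts; the
    p-value sums those no more probable than the observed configuration).
    ``method="chisq"`` gives the 1-df goodness-of-fit chi-square instead.
    Monomorphic SNPs return p = 1.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("all genotypes missing")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    if method == "chisq":
        p = n_a / (2 * n)
        expected = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        observed = np.array([n_hom_a, n_het, n_hom_b])
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        return float(stats.chi2.sf(chi2, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE test method {method!r}")

    rare = min(n_a, n_b)  # conditional on the minor-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | n, rare) up to a constant, via log-factorials
    lf = special.gammaln
    n_rr = (rare - hets) // 2
    n_cc = (n - hets - n_rr)
    logp = (hets * np.log(2) - lf(hets + 1) - lf(n_rr + 1) - lf(n_cc + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_het)]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def _call_rate(genotypes: np.ndarray, axis: int) -> np.ndarray:
    return 1.0 - np.mean(genotypes == MISSING, axis=axis)


def _maf(genotypes: np.ndarray) -> np.ndarray:
    g = np.ma.masked_equal(genotypes, MISSING)
    freq = np.asarray(g.mean(axis=0)) / 2.0
    return np.minimum(freq, 1.0 - freq)


def x_heterozygosity(cohort: Cohort, panel: SnpPanel) -> np.ndarray:
    """Per-individual heterozygosity over chromosome-X SNPs (NaN if none)."""
    x_snps = np.flatnonzero(panel.chromosome.astype(str) == "X")
    if len(x_snps) == 0:
        return np.full(cohort.n_individuals, np.nan)
    g = cohort.genotypes[:, x_snps]
    called = g != MISSING
    with np.errstate(invalid="ignore"):
        return np.where(called.sum(axis=1) > 0,
                        (g == 1).sum(axis=1) / np.maximum(called.sum(axis=1), 1),
                        np.nan)


def infer_sex(cohort: Cohort, panel: SnpPanel, thresholds: QcThresholds) -> np.ndarray:
    """1 male / 2 female / 0 ambiguous, from X heterozygosity."""
    het = x_heterozygosity(cohort, panel)
    out = np.zeros(cohort.n_individuals, dtype=np.int8)
    out[het < thresholds.male_het_max] = 1
    out[het > thresholds.female_het_min] = 2
    return out


def individual_qc(cohort: Cohort, panel: SnpPanel,
                  thresholds: QcThresholds | None = None) -> QcReport:
    """Individual-level filters: call rate, then sex concordance."""
    th = thresholds or QcThresholds()
    report = QcReport(cohort.n_snps, cohort.n_individuals)
    alive = np.ones(cohort.n_individuals, dtype=bool)

    call = _call_rate(cohort.genotypes, axis=1)
    bad = call < th.ind_call_min
    report.removed_individuals["ind_call"] = np.flatnonzero(bad)
    alive &= ~bad

    inferred = infer_sex(cohort, panel, th)
    mismatch = (inferred != 0) & (cohort.sex != 0) & (inferred != cohort.sex)
    mismatch &= alive
    report.removed_individuals["sex_mismatch"] = np.flatnonzero(mismatch)
    alive &= ~mismatch

    if not alive.any():
        raise ValueError("individual QC removed every individual")
    report.kept_individuals = np.flatnonzero(alive)
    report.kept_snps = np.arange(cohort.n_snps)
    return report


def snp_qc(cohort: Cohort, panel: SnpPanel,
           thresholds: QcThresholds | None = None) -> QcReport:
    """SNP-level filters in order: ambiguity, call rate, MAF, HWE."""
    th = thresholds or QcThresholds()
    report = QcReport(cohort.n_snps, cohort.n_individuals)
    alive = np.zeros(cohort.n_snps, dtype=bool)
    alive[filter_ambiguous(panel)] = True
    report.removed_snps["ambiguous"] = np.flatnonzero(~alive)

    call = _call_rate(cohort.genotypes, axis=0)
    bad = (call < th.snp_call_min) & alive
    report.removed_snps["snp_call"] = np.flatnonzero(bad)
    alive &= ~bad

    maf = _maf(cohort.genotypes)
    bad = (maf <= th.maf_min) & alive
    report.removed_snps["maf"] = np.flatnonzero(bad)
    alive &= ~bad

    hwe_bad = []
    for j in np.flatnonzero(alive):
        g = cohort.genotypes[:, j]
        counts = [(g == 2).sum(), (g == 1).sum(), (g == 0).sum()]
        if hwe_test(*counts, method=th.hwe_method) <= th.hwe_p_min:
            hwe_bad.append(j)
    report.removed_snps["hwe"] = np.array(hwe_bad, dtype=int)
    alive[hwe_bad] = False

    if not alive.any():
        raise ValueError("SNP QC removed every SNP")
    report.kept_snps = np.flatnonzero(alive)
    report.kept_individuals = np.arange(cohort.n_individuals)
    return report


def run_qc(cohort: Cohort, panel: SnpPanel,
           thresholds: QcThresholds | None = None
           ) -> tuple[Cohort, SnpPanel, QcReport]:
    """Full chain: individual call rate, sex concordance, then SNP filters."""
    th = thresholds or QcThresholds()
    ind_rep = individual_qc(cohort, panel, th)
    trimmed = cohort.subset(individuals=ind_rep.kept_individuals)
    snp_rep = snp_qc(trimmed, panel, th)

    report = QcReport(cohort.n_snps, cohort.n_individuals)
    report.removed_individuals = ind_rep.removed_individuals
    report.removed_snps = snp_rep.removed_snps
    report.kept_individuals = ind_rep.kept_individuals
    report.kept_snps = snp_rep.kept_snps
    out = trimmed.subset(snps=report.kept_snps)
    return out, panel.subset(report.kept_snps), report


def select_ancestry_snps(panel: SnpPanel, cohort: Cohort,
                         thresholds: QcThresholds | None = None) -> np.ndarray:
    """High-quality, common, widely spaced SNPs for ancestry analysis.

    Greedy left-to-right scan per chromosome keeping SNPs with near-perfect
    call rate, MAF above the ancestry floor and at least the configured
    spacing from the previously kept SNP.
    """
    th = thresholds or QcThresholds()
    call = _call_rate(cohort.genotypes, axis=0)
    maf = _maf(cohort.genotypes)
    eligible = (call >= th.ancestry_call_min) & (maf > th.ancestry_maf_min)
    kept = []
    for chrom in np.unique(panel.chromosome.astype(str)):
        idx = np.flatnonzero((panel.chromosome.astype(str) == chrom) & eligible)
        idx = idx[np.argsort(panel.position[idx])]
        last = -np.inf
        for j in idx:
            if panel.position[j] - last >= th.ancestry_spacing_bp:
                kept.append(j)
                last = panel.position[j]
    return np.array(sorted(kept), dtype=int)


def intersect_panels(panels: list[SnpPanel]) -> list[str]:
    """SNP ids present on every panel, with allele-consistency checking.

    Allele pairs must match across panels either directly or after a strand
    flip (complementing both alleles); an unresolvable mismatch raises.
    Ambiguous SNPs should be removed beforehand (a flip is undetectable).
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to intersect")
    id_sets = [dict(zip(p.snp_id, zip(p.allele_a, p.allele_b))) for p in panels]
    common = set(id_sets[0])
    for s in id_sets[1:]:
        common &= set(s)
    out = []
    for snp in sorted(common):
        ref = frozenset(map(str.upper, id_sets[0][snp]))
        for s in id_sets[1:]:
            pair = frozenset(map(str.upper, s[snp]))
            flipped = frozenset(_COMPLEMENT[x] for x in pair)
            if pair != ref and flipped != ref:
                raise ValueError(
                    f"SNP {snp}: alleles {sorted(pair)} incompatible with "
                    f"{sorted(ref)} even after strand flip"
                )
        out.append(snp)
    return out
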