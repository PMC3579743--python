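"""Liability-threshold family simulator with ascertainment.

The quantitative-genetics machinery behind the expected heritabilities of
parents, unaffected siblings and pseudo-controls under simplex/multiplex
recruitment: additive per-SNP liability effects, nuclear families with
Mendelian transmission, rejection sampling on affection status, optional
assortative mating, pseudo-control construction from untransmitted alleles,
and the selection-differential / response estimator h2_hat = R / S.

Liability is y = G + e with G the additive genetic value over n SNPs
(variance h2 by construction) and e ~ Normal(0, 1 - h2); an individual is
affected when y reaches the upper-K standard-normal quantile (2.326 for the
1% prevalence used throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .panels import Cohort, as_rng

ROLES = ("proband", "father", "mother", "sibling", "pseudo_control")
SCENARIOS = ("screened_simplex", "simplex_unscreened", "multiplex_unscreened", "mixture_60_40")
MATING_MODES = ("random", "assortative", "assortative_per_snp", "assortative_per_family")

#: Default number of children per scenario: screened simplex ascertainment
#: needs an unaffected designated sibling, multiplex needs a second affected
#: child; the unscreened simplex families are parent-parent-child trios.
_DEFAULT_CHILDREN = {
    "screened_simplex": 2,
    "simplex_unscreened": 1,
    "multiplex_unscreened": 2,
}


def liability_threshold(prevalence: float) -> float:
    """Upper-``prevalence`` quantile of the standard normal (2.326 at 1%)."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    return float(stats.norm.isf(prevalence))


@dataclass
class EffectPanel:
    """Per-SNP allele-substitution effects defining additive liability.

    Relative SNP importances w are uniform draws normalized to sum to one;
    the substitution effect a_i = sqrt(w_i h2 / (2 p_i (1 - p_i))) makes the
    per-SNP additive variances 2 p_i (1 - p_i) a_i^2 sum exactly to h2.
    ``mu_G`` centers the genetic value: G = sum_i x_i a_i - mu_G has mean
    zero in a random-mating population (E[x_i] = 2 p_i).
    """

    p: np.ndarray
    t: np.ndarray
    w: np.ndarray
    a: np.ndarray
    h2: float
    mu_G: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("effect-panel frequencies must lie strictly in (0, 1)")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        var = float(np.sum(2 * self.p * (1 - self.p) * self.a**2))
        if abs(var - self.h2) > 1e-10:
            raise ValueError("per-SNP variances do not sum to h2")

    @property
    def n(self) -> int:
        return len(self.p)

    @property
    def T(self) -> float:
        return float(self.t.sum())

    def genetic_value(self, genotype: np.ndarray) -> np.ndarray | float:
        """Additive genetic value G = sum_i x_i a_i - mu_G.

        Accepts a single allele-count vector or an (individuals, SNPs)
        matrix; returns a scalar or a vector accordingly.
        """
        x = np.asarray(genotype)
        if x.shape[-1] != self.n:
            raise ValueError("genotype length does not match the effect panel")
        g = x.astype(np.float64) @ self.a - self.mu_G
        return float(g) if x.ndim == 1 else g


def draw_effect_panel(
    n: int,
    h2: float,
    p: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    maf_range: tuple[float, float] = (0.01, 0.99),
) -> EffectPanel:
    """Draw an effect panel: t ~ U(0,1), w = t/T, a = sqrt(w h2 / 2pq)."""
    rng = as_rng(seed)
    if p is None:
        p = rng.uniform(*maf_range, size=n)
    p = np.asarray(p, dtype=float)
    if len(p) != n:
        raise ValueError("frequency vector length does not match n")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    t = rng.uniform(0.0, 1.0, size=n)
    w = t / t.sum()
    a = np.sqrt(w * h2 / (2 * p * (1 - p)))
    mu_G = float(np.sum(2 * p * a))
    return EffectPanel(p=p, t=t, w=w, a=a, h2=float(h2), mu_G=mu_G)


def genetic_value(genotype: np.ndarray, effects: EffectPanel):
    return effects.genetic_value(genotype)


def assign_phenotype(
    G: np.ndarray | float,
    h2: float,
    tau: float,
    seed: int | np.random.Generator | None = None,
):
    """Add the environmental deviate and threshold the liability.

    e ~ Normal(0, 1 - h2), y = G + e, affected iff y >= tau. Returns
    (e, y, affected) with shapes matching G.
    """
    rng = as_rng(seed)
    G = np.asarray(G, dtype=float)
    e = rng.normal(0.0, np.sqrt(1.0 - h2), size=G.shape)
    y = G + e
    return e, y, y >= tau


# ---------------------------------------------------------------------------
# Single-family object API (explicit transmission bookkeeping)
# ---------------------------------------------------------------------------


@dataclass
class SimChild:
    genotype: np.ndarray  # allele counts over the effect panel's SNPs
    transmitted_father: np.ndarray  # the paternal allele received, in {0, 1}
    transmitted_mother: np.ndarray


@dataclass
class SimFamily:
    """One nuclear family with phased parents and recorded transmissions."""

    father: np.ndarray  # (2, n) haplotypes in {0, 1}
    mother: np.ndarray
    children: list[SimChild]
    pseudo_control: np.ndarray | None = None
    G: dict = field(default_factory=dict)
    e: dict = field(default_factory=dict)
    y: dict = field(default_factory=dict)
    affected: dict = field(default_factory=dict)

    def member_genotype(self, member: str) -> np.ndarray:
        if member == "father":
            return self.father.sum(axis=0)
        if member == "mother":
            return self.mother.sum(axis=0)
        if member == "pseudo_control":
            if self.pseudo_control is None:
                raise ValueError("pseudo-control not constructed")
            return self.pseudo_control
        if member.startswith("child"):
            return self.children[int(member[5:]) - 1].genotype
        raise KeyError(member)


def assortative_mother(
    father: np.ndarray,
    p: np.ndarray,
    seed: int | np.random.Generator | None = None,
    mode: str = "per_snp",
) -> np.ndarray:
    """Assign a maternal genotype by the fair-coin assortative rule.

    Heads, the mother's genotype is drawn independently from the allele
    frequencies; tails, it is set equal to the father's. ``mode`` selects
    whether the coin is tossed once per SNP (default) or once per family.
    """
    rng = as_rng(seed)
    n = father.shape[1]
    mother = np.empty_like(father)
    mother[0] = rng.random(n) < p
    mother[1] = rng.random(n) < p
    if mode == "per_family":
        if rng.random() < 0.5:
            mother = father.copy()
    elif mode == "per_snp":
        tails = rng.random(n) < 0.5
        mother[:, tails] = father[:, tails]
    else:
        raise ValueError(f"unknown assortative mode {mode!r}")
    return mother


def _coin_mode(mating: str) -> str | None:
    if mating == "random":
        return None
    if mating in ("assortative", "assortative_per_snp"):
        return "per_snp"
    if mating == "assortative_per_family":
        return "per_family"
    raise ValueError(f"unknown mating mode {mating!r}")


def simulate_family(
    effects: EffectPanel,
    n_children: int = 2,
    mating: str = "random",
    seed: int | np.random.Generator | None = None,
    prevalence: float = 0.01,
) -> SimFamily:
    """Simulate one family: parents, Mendelian children, pseudo-control.

    Parental haplotypes are Bernoulli draws at the panel frequencies (or the
    assortative coin rule for the mother); each child receives one allele
    per SNP from each parent, chosen with probability one half, and the
    transmitted alleles are recorded. The pseudo-control is built against
    child 1. Liabilities and affection status are assigned to every member,
    the pseudo-control receiving its own environmental deviate.
    """
    if n_children not in (1, 2):
        raise ValueError("n_children must be 1 or 2")
    rng = as_rng(seed)
    n = effects.n
    tau = liability_threshold(prevalence)

    father = np.vstack([rng.random(n) < effects.p, rng.random(n) < effects.p]).astype(np.int8)
    mode = _coin_mode(mating)
    if mode is None:
        mother = np.vstack([rng.random(n) < effects.p, rng.random(n) < effects.p]).astype(np.int8)
    else:
        mother = assortative_mother(father, effects.p, rng, mode=mode)

    children = []
    for _ in range(n_children):
        pick_f = (rng.random(n) < 0.5).astype(np.int8)  # 0 -> haplotype 0
        pick_m = (rng.random(n) < 0.5).astype(np.int8)
        tf = father[pick_f, np.arange(n)]
        tm = mother[pick_m, np.arange(n)]
        children.append(SimChild(genotype=(tf + tm).astype(np.int8),
                                 transmitted_father=tf, transmitted_mother=tm))

    fam = SimFamily(father=father, mother=mother, children=children)
    fam.pseudo_control = make_pseudo_control(fam, child_index=0)

    members = {"father": fam.member_genotype("father"),
               "mother": fam.member_genotype("mother"),
               "pseudo_control": fam.pseudo_control}
    for i in range(n_children):
        members[f"child{i + 1}"] = children[i].genotype
    for name, x in members.items():
        G = effects.genetic_value(x)
        e, y, aff = assign_phenotype(G, effects.h2, tau, rng)
        fam.G[name], fam.e[name], fam.y[name], fam.affected[name] = G, float(e), float(y), bool(aff)
    return fam


def make_pseudo_control(family: SimFamily, child_index: int = 0) -> np.ndarray:
    """Genotype assembled from the alleles each parent did not transmit.

    Per SNP the pseudo-control carries the father's untransmitted allele
    plus the mother's, so child + pseudo-control = father + mother in
    allele counts at every SNP.
    """
    if child_index >= len(family.children):
        raise IndexError("no such child in the family")
    child = family.children[child_index]
    if child.transmitted_father is None or child.transmitted_mother is None:
        raise ValueError("transmission record missing for this child")
    untrans_f = family.father.sum(axis=0) - child.transmitted_father
    untrans_m = family.mother.sum(axis=0) - child.transmitted_mother
    return (untrans_f + untrans_m).astype(np.int8)


# ---------------------------------------------------------------------------
# Scenario specification and chunk-vectorized rejection sampling
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Recruitment scenario for the rejection-sampling ascertainment.

    scenario:
      screened_simplex        child 1 affected; father, mother, child 2 unaffected
      simplex_unscreened  child 1 affected, trio, no other restriction
      multiplex_unscreened  both children affected, no parental restriction
      mixture_60_40       60% unscreened simplex + 40% unscreened multiplex
    """

    scenario: str
    n_families: int = 1000
    h2: float = 0.5
    prevalence: float = 0.01
    mating: str = "random"
    n_replicates: int = 100
    seed: int | None = None
    n_children: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.mating not in MATING_MODES:
            raise ValueError(f"unknown mating mode {self.mating!r}")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_children is None and self.scenario != "mixture_60_40":
            self.n_children = _DEFAULT_CHILDREN[self.scenario]

    @property
    def tau(self) -> float:
        return liability_threshold(self.prevalence)


@dataclass
class FamilyBlock:
    """Column-wise container for a set of accepted families.

    Genotypes are allele-count matrices (families x SNPs); liabilities are
    per-member vectors. Trio families (no designated sibling) carry NaN in
    the child-2 columns and -1 genotypes.
    """

    effects: EffectPanel
    tau: float
    X: dict[str, np.ndarray]  # father, mother, child1, child2, pseudo_control
    G: dict[str, np.ndarray]
    y: dict[str, np.ndarray]
    affected: dict[str, np.ndarray]
    has_sibling: np.ndarray
    n_candidates: int = 0  # candidate families examined during ascertainment

    @property
    def n_families(self) -> int:
        return len(self.has_sibling)

    @property
    def acceptance_rate(self) -> float:
        if self.n_candidates == 0:
            raise ValueError("no candidate count recorded for this block")
        return self.n_families / self.n_candidates

    def role_liability(self, role: str) -> np.ndarray:
        member = {"proband": "child1", "father": "father", "mother": "mother",
                  "sibling": "child2", "pseudo_control": "pseudo_control"}[role]
        y = self.y[member]
        if role == "sibling":
            if not self.has_sibling.any():
                raise ValueError("no families with a designated sibling")
            return y[self.has_sibling]
        return y

    def to_cohort(self, member: str, phenotype: int = 1) -> Cohort:
        """Export one member per family as a cohort (e.g. for GREML contrasts)."""
        x = self.X[member]
        keep = np.flatnonzero((x >= 0).all(axis=1))
        nf = len(keep)
        return Cohort(
            x[keep],
            np.full(nf, phenotype, dtype=np.int8),
            np.zeros(nf, dtype=np.int8),
            np.array([f"FAM{i + 1}" for i in keep], dtype=object),
            np.array([f"{member}{i + 1}" for i in keep], dtype=object),
        )


def _bern(rng, buf, p32):
    rng.random(out=buf, dtype=np.float32)
    return buf < p32


def _haplo_to_G(h1, h2_, a32, mu):
    return (h1.astype(np.int8) + h2_).astype(np.float32) @ a32 - np.float32(mu)


def ascertain(
    spec: ScenarioSpec,
    effects: EffectPanel,
    seed: int | np.random.Generator | None = None,
    chunk_size: int = 25_000,
    max_attempts: int = 1_000_000_000,
) -> FamilyBlock:
    """Rejection-sample families until ``spec.n_families`` are accepted.

    Candidate families are generated in vectorized chunks; the proband is
    simulated and screened first, and the remaining family members are only
    materialized for candidates whose proband is affected (their genotypes
    are independent of the proband's affection status given the parents, so
    the deferral leaves the accepted distribution exact).
    """
    if abs(effects.h2 - spec.h2) > 1e-12:
        raise ValueError("effect panel h2 does not match the scenario spec")
    rng = as_rng(spec.seed if seed is None else seed)

    if spec.scenario == "mixture_60_40":
        n_simplex = int(round(0.6 * spec.n_families))
        sub_s = ScenarioSpec("simplex_unscreened", n_simplex, spec.h2,
                             spec.prevalence, spec.mating, spec.n_replicates)
        sub_m = ScenarioSpec("multiplex_unscreened", spec.n_families - n_simplex,
                             spec.h2, spec.prevalence, spec.mating, spec.n_replicates)
        b1 = ascertain(sub_s, effects, rng, chunk_size, max_attempts)
        b2 = ascertain(sub_m, effects, rng, chunk_size, max_attempts)
        return _concat_blocks([b1, b2])

    n = effects.n
    tau = spec.tau
    p32 = effects.p.astype(np.float32)
    a32 = effects.a.astype(np.float32)
    mu = effects.mu_G
    sd_e = float(np.sqrt(1.0 - effects.h2))
    coin = _coin_mode(spec.mating)
    half = np.float32(0.5)
    two_children = spec.scenario in ("screened_simplex", "multiplex_unscreened") or spec.n_children == 2

    buf = np.empty((chunk_size, n), dtype=np.float32)
    parts: list[dict] = []
    got = 0
    attempts = 0
    while got < spec.n_families:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"ascertainment for scenario {spec.scenario!r} did not accept "
                f"{spec.n_families} families within {max_attempts} candidates"
            )
        attempts += chunk_size
        f1 = _bern(rng, buf, p32)
        f2 = _bern(rng, buf, p32)
        m1 = _bern(rng, buf, p32)
        m2 = _bern(rng, buf, p32)
        if coin == "per_family":
            tails = rng.random(chunk_size) < 0.5
            m1[tails] = f1[tails]
            m2[tails] = f2[tails]
        elif coin == "per_snp":
            tails = _bern(rng, buf, half)
            m1 = np.where(tails, f1, m1)
            m2 = np.where(tails, f2, m2)

        t1f = np.where(_bern(rng, buf, half), f1, f2)
        t1m = np.where(_bern(rng, buf, half), m1, m2)
        Gc1 = _haplo_to_G(t1f, t1m, a32, mu)
        yc1 = Gc1 + rng.normal(0.0, sd_e, chunk_size)
        k = np.flatnonzero(yc1 >= tau)  # every scenario requires an affected proband
        if len(k) == 0:
            continue

        # Remaining members, survivors only.
        Gf = _haplo_to_G(f1[k], f2[k], a32, mu)
        Gm = _haplo_to_G(m1[k], m2[k], a32, mu)
        yf = Gf + rng.normal(0.0, sd_e, len(k))
        ym = Gm + rng.normal(0.0, sd_e, len(k))
        if two_children:
            s2f = rng.random((len(k), n)) < 0.5
            s2m = rng.random((len(k), n)) < 0.5
            t2f = np.where(s2f, f1[k], f2[k])
            t2m = np.where(s2m, m1[k], m2[k])
            Gc2 = _haplo_to_G(t2f, t2m, a32, mu)
            yc2 = Gc2 + rng.normal(0.0, sd_e, len(k))
        Gpc = Gf + Gm - Gc1[k]
        ypc = Gpc + rng.normal(0.0, sd_e, len(k))

        if spec.scenario == "multiplex_unscreened":
            ok = yc2 >= tau
        elif spec.scenario == "screened_simplex":
            ok = (yf < tau) & (ym < tau) & (yc2 < tau)
        else:
            ok = np.ones(len(k), dtype=bool)
        if not ok.any():
            continue
        sel = np.flatnonzero(ok)
        kk = k[sel]

        part = {
            "Xf": (f1[kk].astype(np.int8) + f2[kk]),
            "Xm": (m1[kk].astype(np.int8) + m2[kk]),
            "Xc1": (t1f[kk].astype(np.int8) + t1m[kk]),
            "Gf": Gf[sel], "Gm": Gm[sel], "Gc1": Gc1[kk], "Gpc": Gpc[sel],
            "yf": yf[sel], "ym": ym[sel], "yc1": yc1[kk], "ypc": ypc[sel],
        }
        if two_children:
            part["Xc2"] = (t2f[sel].astype(np.int8) + t2m[sel])
            part["Gc2"] = Gc2[sel]
            part["yc2"] = yc2[sel]
        part["Xpc"] = part["Xf"] + part["Xm"] - part["Xc1"]
        parts.append(part)
        got += len(kk)

    def take(key):
        return np.concatenate([pt[key] for pt in parts])[: spec.n_families]

    nf = spec.n_families
    X = {"father": take("Xf"), "mother": take("Xm"), "child1": take("Xc1"),
         "pseudo_control": take("Xpc")}
    G = {"father": take("Gf"), "mother": take("Gm"), "child1": take("Gc1"),
         "pseudo_control": take("Gpc")}
    y = {"father": take("yf"), "mother": take("ym"), "child1": take("yc1"),
         "pseudo_control": take("ypc")}
    if two_children:
        X["child2"] = take("Xc2")
        G["child2"] = take("Gc2")
        y["child2"] = take("yc2")
        has_sib = np.ones(nf, dtype=bool)
    else:
        X["child2"] = np.full((nf, n), -1, dtype=np.int8)
        G["child2"] = np.full(nf, np.nan)
        y["child2"] = np.full(nf, np.nan)
        has_sib = np.zeros(nf, dtype=bool)
    affected = {m: (np.where(np.isnan(v), np.nan, v >= tau) if m == "child2" else v >= tau)
                for m, v in y.items()}
    return FamilyBlock(effects=effects, tau=tau, X=X, G=G, y=y,
                       affected=affected, has_sibling=has_sib,
                       n_candidates=attempts)


def _concat_blocks(blocks: list[FamilyBlock]) -> FamilyBlock:
    b0 = blocks[0]
    keys = b0.X.keys()
    return FamilyBlock(
        effects=b0.effects,
        tau=b0.tau,
        X={k: np.concatenate([b.X[k] for b in blocks]) for k in keys},
        G={k: np.concatenate([b.G[k] for b in blocks]) for k in keys},
        y={k: np.concatenate([b.y[k] for b in blocks]) for k in keys},
        affected={k: np.concatenate([b.affected[k] for b in blocks]) for k in keys},
        has_sibling=np.concatenate([b.has_sibling for b in blocks]),
        n_candidates=sum(b.n_candidates for b in blocks),
    )


# ---------------------------------------------------------------------------
# Selection differential / response estimator
# ---------------------------------------------------------------------------


class RelativeH2(NamedTuple):
    S: float  # mean proband liability (selection differential)
    R: float  # mean liability of the role group (response)
    h2_hat: float  # R / S


def estimate_relative_h2(
    block: FamilyBlock,
    role: str,
    proband_estimator: str = "mean_ratio",
) -> RelativeH2:
    """Heritability attributable to a relative class: h2_hat = R / S.

    S is the mean liability of the ascertained probands; R is the mean
    liability of the named role. For role="proband" the ratio contrasts the
    probands' mean genetic value with their mean liability (the recovery
    check that the simulator reproduces the configured h2); the
    variance-based alternative inverts the reduction of genetic variance in
    the selected group under single-threshold truncation.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    S = float(np.mean(block.y["child1"]))
    if abs(S) < 1e-6:
        raise ZeroDivisionError("no selection differential: S is zero")
    if role == "proband":
        if proband_estimator == "mean_ratio":
            R = float(np.mean(block.G["child1"]))
        elif proband_estimator == "variance":
            return RelativeH2(S, float(np.var(block.G["child1"])),
                              proband_h2_from_variance(block))
        else:
            raise ValueError(f"unknown proband estimator {proband_estimator!r}")
    else:
        R = float(np.mean(block.role_liability(role)))
    return RelativeH2(S, R, R / S)


def proband_h2_from_variance(block: FamilyBlock) -> float:
    """Recover h2 from the reduction in genetic variance among probands.

    Under truncation selection at tau with intensity i = S, the liability
    variance shrinks by k = i (i - tau) and the genetic variance among the
    selected is h2 (1 - h2 k); solving the quadratic for h2 gives the
    estimator. Only meaningful when selection acts on the proband alone.
    """
    S = float(np.mean(block.y["child1"]))
    k = S * (S - block.tau)
    v = float(np.var(block.G["child1"]))
    disc = 1.0 - 4.0 * k * v
    # the discriminant sits near zero when h2*k ~ 1/2; sampling noise can
    # push it slightly negative, in which case the root h2 = 1/(2k) is the
    # continuous solution
    if disc < -0.05:
        raise ValueError("variance-based recovery has no real solution")
    return (1.0 - np.sqrt(max(disc, 0.0))) / (2.0 * k)


def expected_h2_experiment(
    scenarios=("simplex_unscreened",),
    h2_values=(0.5, 0.75),
    matings=("random",),
    n_families: int = 1000,
    n_replicates: int = 100,
    roles=ROLES,
    n_snps: int = 1000,
    prevalence: float = 0.01,
    seed: int | None = None,
    chunk_size: int = 25_000,
) -> pd.DataFrame:
    """Grid of scenarios x h2 x mating: per-replicate S, R and R/S per role.

    A fresh effect panel is drawn for every replicate (the replicate spread
    therefore includes the variability of the simulated genetic
    architecture). Returns a tidy frame with one row per cell x replicate x
    role.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for scenario in scenarios:
        for h2 in h2_values:
            for mating in matings:
                cell_rng = np.random.default_rng(ss.spawn(1)[0])
                for rep in range(n_replicates):
                    effects = draw_effect_panel(n_snps, h2, seed=cell_rng)
                    spec = ScenarioSpec(scenario, n_families, h2, prevalence, mating)
                    block = ascertain(spec, effects, cell_rng, chunk_size=chunk_size)
                    for role in roles:
                        if role == "sibling" and not block.has_sibling.any():
                            continue
                        res = estimate_relative_h2(block, role)
                        rows.append({"scenario": scenario, "h2": h2, "mating": mating,
                                     "role": role, "replicate": rep,
                                     "S": res.S, "R": res.R, "h2_hat": res.h2_hat})
    return pd.DataFrame(rows)


def summarize_expected_h2(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of R/S across replicates per scenario x h2 x mating x role."""
    g = table.groupby(["scenario", "h2", "mating", "role"], sort=False)["h2_hat"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["sem"] = out["std"] / np.sqrt(out["count"])
    return out
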