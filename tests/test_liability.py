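"""Liability-threshold simulator: effects, families, ascertainment, R/S."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import liabherit as lh
from liabherit.liability import FamilyBlock, RelativeH2, SimChild, SimFamily


class TestEffectPanel:
    def test_two_snp_closed_form(self, two_snp_effects):
        ep = two_snp_effects
        assert ep.w == pytest.approx([0.5, 0.5])
        assert ep.a == pytest.approx([0.70711, 0.70711], abs=1e-5)
        assert ep.mu_G == pytest.approx(1.41421, abs=1e-5)

    def test_genetic_value_examples(self, two_snp_effects):
        # heterozygote at p = 0.5 sits at the population mean
        assert two_snp_effects.genetic_value(np.array([1, 1])) == pytest.approx(0.0)
        assert two_snp_effects.genetic_value(np.array([2, 2])) == pytest.approx(1.41421, abs=1e-5)

    @given(n=st.integers(2, 80), h2=st.floats(0.0, 1.0), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_variance_normalization_invariant(self, n, h2, seed):
        ep = lh.draw_effect_panel(n, h2, seed=seed)
        assert float(np.sum(2 * ep.p * (1 - ep.p) * ep.a**2)) == pytest.approx(h2, abs=1e-10)
        assert np.all(ep.a >= 0)
        assert float(ep.w.sum()) == pytest.approx(1.0)

    def test_zero_heritability_zeroes_all_effects(self):
        ep = lh.draw_effect_panel(20, 0.0, seed=1)
        assert np.all(ep.a == 0)

    def test_population_moments_of_genetic_value(self, rng):
        ep = lh.draw_effect_panel(500, 0.5, seed=2)
        x = (rng.random((100_000, 500)) < ep.p) * 1 + (rng.random((100_000, 500)) < ep.p)
        G = ep.genetic_value(x)
        assert np.mean(G) == pytest.approx(0.0, abs=0.01)
        assert np.var(G) == pytest.approx(0.5, abs=0.02)

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError):
            lh.draw_effect_panel(3, 0.5, p=np.array([0.0, 0.5, 0.5]))

    def test_length_mismatch_rejected(self, two_snp_effects):
        with pytest.raises(ValueError):
            two_snp_effects.genetic_value(np.array([1, 1, 1]))


class TestPhenotypeAssignment:
    def test_threshold_is_upper_one_percent_quantile(self):
        assert lh.liability_threshold(0.01) == pytest.approx(2.326, abs=5e-4)

    def test_full_heritability_means_no_environment(self, rng):
        G = rng.normal(size=100)
        e, y, aff = lh.assign_phenotype(G, 1.0, 2.326, seed=3)
        assert np.all(e == 0)
        assert np.array_equal(y, G)

    def test_unscreened_affected_fraction(self, rng):
        G = np.zeros(200_000)
        _, _, aff = lh.assign_phenotype(G, 0.0, lh.liability_threshold(0.01), seed=4)
        assert np.mean(aff) == pytest.approx(0.01, abs=0.002)


class TestFamilySimulation:
    def test_transmission_bookkeeping(self):
        fam = lh.simulate_family(lh.draw_effect_panel(50, 0.5, seed=5), seed=6)
        for child in fam.children:
            assert np.array_equal(child.genotype,
                                  child.transmitted_father + child.transmitted_mother)
            # each transmitted allele is one of the parent's two alleles
            assert np.all((child.transmitted_father == fam.father[0])
                          | (child.transmitted_father == fam.father[1]))
            assert np.all((child.transmitted_mother == fam.mother[0])
                          | (child.transmitted_mother == fam.mother[1]))

    def test_mendelian_neutrality_at_half_frequency(self):
        ep = lh.draw_effect_panel(1, 0.5, p=np.array([0.5]), seed=7)
        counts = [lh.simulate_family(ep, n_children=1, seed=s).children[0].genotype[0]
                  for s in range(3000)]
        assert np.mean(counts) / 2 == pytest.approx(0.5, abs=0.03)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_identity_per_family(self, seed):
        ep = lh.draw_effect_panel(30, 0.5, seed=99)
        fam = lh.simulate_family(ep, n_children=2, seed=seed)
        total = fam.member_genotype("father") + fam.member_genotype("mother")
        assert np.array_equal(fam.children[0].genotype + fam.pseudo_control, total)

    def test_affection_matches_threshold(self):
        ep = lh.draw_effect_panel(40, 0.5, seed=8)
        fam = lh.simulate_family(ep, seed=9, prevalence=0.01)
        tau = lh.liability_threshold(0.01)
        for member, y in fam.y.items():
            assert fam.affected[member] == (y >= tau)


class TestPseudoControl:
    def test_untransmitted_allele_bookkeeping(self):
        # father 0/1 transmitted 1; mother 1/1 transmitted 1 -> pc = 0 + 1
        fam = SimFamily(father=np.array([[0], [1]], dtype=np.int8),
                        mother=np.array([[1], [1]], dtype=np.int8),
                        children=[SimChild(np.array([2], dtype=np.int8),
                                           np.array([1], dtype=np.int8),
                                           np.array([1], dtype=np.int8))])
        assert lh.make_pseudo_control(fam, 0)[0] == 1

    def test_homozygous_parents_make_pseudo_control_equal_child(self):
        ep = lh.draw_effect_panel(10, 0.5, p=np.full(10, 0.5), seed=10)
        for s in range(40):
            fam = lh.simulate_family(ep, seed=s)
            hom = (fam.father[0] == fam.father[1]) & (fam.mother[0] == fam.mother[1])
            pc = lh.make_pseudo_control(fam, 0)
            assert np.array_equal(pc[hom], fam.children[0].genotype[hom])

    def test_missing_transmission_record_raises(self):
        fam = SimFamily(father=np.zeros((2, 3), dtype=np.int8),
                        mother=np.zeros((2, 3), dtype=np.int8),
                        children=[SimChild(np.zeros(3, dtype=np.int8), None, None)])
        with pytest.raises(ValueError):
            lh.make_pseudo_control(fam, 0)
        with pytest.raises(IndexError):
            lh.make_pseudo_control(fam, 5)


class TestAssortativeMating:
    def test_per_family_coin_copies_whole_genotype_or_none(self, rng):
        ep = lh.draw_effect_panel(120, 0.5, seed=11)
        father = np.vstack([rng.random(120) < ep.p, rng.random(120) < ep.p]).astype(np.int8)
        copies = 0
        for s in range(300):
            mom = lh.assortative_mother(father, ep.p, seed=s, mode="per_family")
            if np.array_equal(mom, father):
                copies += 1
            else:  # heads: independent draw, essentially never all-equal
                assert np.any(mom.sum(axis=0) != father.sum(axis=0))
        assert 0.4 < copies / 300 < 0.6

    def test_per_snp_coin_copies_about_half_the_sites(self, rng):
        ep = lh.draw_effect_panel(400, 0.5, seed=12)
        father = np.vstack([rng.random(400) < ep.p, rng.random(400) < ep.p]).astype(np.int8)
        fracs = []
        for s in range(100):
            mom = lh.assortative_mother(father, ep.p, seed=s, mode="per_snp")
            fracs.append(np.mean(np.all(mom == father, axis=0)))
        # half the sites are exact copies; the rest match by chance sometimes
        assert 0.55 < np.mean(fracs) < 0.85

    @pytest.mark.parametrize("mode", ["per_snp", "per_family"])
    def test_parental_genetic_correlation_is_one_half(self, mode, rng):
        ep = lh.draw_effect_panel(200, 0.5, seed=13)
        Gf, Gm = [], []
        for s in range(4000):
            father = np.vstack([rng.random(200) < ep.p,
                                rng.random(200) < ep.p]).astype(np.int8)
            mom = lh.assortative_mother(father, ep.p, seed=s, mode=mode)
            Gf.append(ep.genetic_value(father.sum(axis=0)))
            Gm.append(ep.genetic_value(mom.sum(axis=0)))
        r = np.corrcoef(Gf, Gm)[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            lh.assortative_mother(np.zeros((2, 3), dtype=np.int8),
                                  np.full(3, 0.5), seed=1, mode="sometimes")


def _block(scenario, h2=0.5, n=400, mating="random", seed=21, n_snps=300, **kw):
    ep = lh.draw_effect_panel(n_snps, h2, seed=seed)
    spec = lh.ScenarioSpec(scenario, n, h2, mating=mating, **kw)
    return lh.ascertain(spec, ep, seed=seed + 1, chunk_size=20_000), ep


class TestAscertainment:
    def test_simplex_rule(self):
        blk, _ = _block("simplex_unscreened")
        assert blk.n_families == 400
        assert np.all(blk.y["child1"] >= blk.tau)
        assert not blk.has_sibling.any()

    def test_screened_quad_rule(self):
        blk, _ = _block("screened_simplex", n=150)
        assert np.all(blk.y["child1"] >= blk.tau)
        for member in ("father", "mother", "child2"):
            assert np.all(blk.y[member] < blk.tau)

    def test_multiplex_rule(self):
        blk, _ = _block("multiplex_unscreened", n=100)
        assert np.all(blk.y["child1"] >= blk.tau)
        assert np.all(blk.y["child2"] >= blk.tau)

    def test_mixture_is_60_40(self):
        blk, _ = _block("mixture_60_40", n=200)
        assert int(blk.has_sibling.sum()) == 80
        assert np.all(blk.X["child2"][~blk.has_sibling] == -1)

    def test_simplex_acceptance_rate_is_prevalence(self):
        blk, _ = _block("simplex_unscreened", n=600, seed=31)
        assert 0.006 < blk.acceptance_rate < 0.015

    def test_conservation_identity_in_blocks(self):
        for scenario in ("simplex_unscreened", "multiplex_unscreened"):
            blk, _ = _block(scenario, n=80, seed=41)
            total = blk.X["father"] + blk.X["mother"]
            assert np.array_equal(blk.X["child1"] + blk.X["pseudo_control"], total)

    def test_block_genetic_values_match_effect_panel(self):
        blk, ep = _block("simplex_unscreened", n=120, seed=51)
        for member in ("father", "mother", "child1", "pseudo_control"):
            G = ep.genetic_value(blk.X[member])
            assert np.allclose(G, blk.G[member], atol=2e-3)

    def test_children_respect_homozygous_parents(self):
        blk, _ = _block("multiplex_unscreened", n=60, seed=61)
        xf, xm, xc = blk.X["father"], blk.X["mother"], blk.X["child1"]
        assert np.all(xc[(xf == 0) & (xm == 0)] == 0)
        assert np.all(xc[(xf == 2) & (xm == 2)] == 2)
        assert np.all(xc[(xf == 2) & (xm == 0)] == 1)

    def test_mismatched_h2_rejected(self):
        ep = lh.draw_effect_panel(50, 0.5, seed=71)
        with pytest.raises(ValueError):
            lh.ascertain(lh.ScenarioSpec("simplex_unscreened", 10, h2=0.75), ep)

    def test_attempt_budget_enforced(self):
        ep = lh.draw_effect_panel(50, 0.5, seed=72)
        spec = lh.ScenarioSpec("multiplex_unscreened", 1000, 0.5, prevalence=0.001)
        with pytest.raises(RuntimeError):
            lh.ascertain(spec, ep, seed=73, chunk_size=5000, max_attempts=10_000)


def _manual_block(yc1, ypc, tau=2.326):
    n = len(yc1)
    z = np.zeros((n, 2), dtype=np.int8)
    ep = lh.draw_effect_panel(2, 0.5, seed=1)
    arrs = lambda v: {m: np.asarray(v, dtype=float) for m in
                      ("father", "mother", "child1", "child2", "pseudo_control")}
    y = arrs(0.0)
    y["child1"] = np.asarray(yc1, dtype=float)
    y["pseudo_control"] = np.asarray(ypc, dtype=float)
    return FamilyBlock(effects=ep, tau=tau,
                       X={m: z for m in y}, G=arrs(0.0), y=y,
                       affected={m: v >= tau for m, v in y.items()},
                       has_sibling=np.ones(n, dtype=bool))


class TestRelativeH2:
    def test_hand_computed_three_family_ratio(self):
        # spreadsheet arithmetic: S = (2.5+3.0+2.6)/3, R = (0.5-0.2+0.9)/3
        blk = _manual_block([2.5, 3.0, 2.6], [0.5, -0.2, 0.9])
        res = lh.estimate_relative_h2(blk, "pseudo_control")
        S = (2.5 + 3.0 + 2.6) / 3
        R = (0.5 - 0.2 + 0.9) / 3
        assert res.S == pytest.approx(S)
        assert res.R == pytest.approx(R)
        assert res.h2_hat == pytest.approx(R / S)

    def test_zero_selection_differential_is_an_error(self):
        blk = _manual_block([1e-9, -1e-9, 0.0], [0.1, 0.1, 0.1])
        with pytest.raises(ZeroDivisionError):
            lh.estimate_relative_h2(blk, "pseudo_control")

    def test_unknown_role_rejected(self):
        blk = _manual_block([2.5, 3.0, 2.6], [0.5, -0.2, 0.9])
        with pytest.raises(ValueError):
            lh.estimate_relative_h2(blk, "uncle")

    def test_sibling_requires_quads(self):
        blk, _ = _block("simplex_unscreened", n=50, seed=81)
        with pytest.raises(ValueError):
            lh.estimate_relative_h2(blk, "sibling")

    def test_proband_recovery_at_small_scale(self):
        blk, _ = _block("simplex_unscreened", n=600, seed=91)
        res = lh.estimate_relative_h2(blk, "proband")
        assert res.h2_hat == pytest.approx(0.5, abs=0.06)

    def test_variance_based_proband_recovery(self):
        blk, _ = _block("simplex_unscreened", n=800, seed=92)
        h2 = lh.liability.proband_h2_from_variance(blk)
        assert h2 == pytest.approx(0.5, abs=0.12)


class TestExperimentTable:
    def test_tidy_output_and_determinism(self):
        kw = dict(scenarios=("simplex_unscreened",), h2_values=(0.5,),
                  matings=("random",), n_families=100, n_replicates=3,
                  n_snps=100, seed=7)
        a = lh.expected_h2_experiment(**kw)
        b = lh.expected_h2_experiment(**kw)
        assert a.equals(b)
        assert set(a.columns) == {"scenario", "h2", "mating", "role",
                                  "replicate", "S", "R", "h2_hat"}
        summary = lh.summarize_expected_h2(a)
        assert set(summary["role"]) == {"proband", "father", "mother", "pseudo_control"}
        assert (summary["count"] == 3).all()
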