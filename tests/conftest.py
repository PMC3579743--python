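import numpy as np
import pytest

import liabherit as lh


@pytest.fixture
def rng():
    return np.random.default_rng(20120915)


@pytest.fixture(scope="session")
def small_panel():
    """60 SNPs spread over chromosomes 1, 2 and X."""
    return lh.simulate_panel(60, maf_range=(0.1, 0.9),
                             chromosomes=["1", "2", "X"], seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    effects = lh.draw_effect_panel(small_panel.n_snps, 0.5, p=small_panel.p, seed=12)
    return lh.simulate_case_control(small_panel, effects, 0.01, 40, 40, seed=13)


@pytest.fixture(scope="session")
def two_snp_effects():
    """The hand-checkable two-SNP panel: equal weights, p = 0.5, h2 = 0.5."""
    p = np.array([0.5, 0.5])
    t = np.array([1.0, 1.0])
    w = t / t.sum()
    a = np.sqrt(w * 0.5 / (2 * p * (1 - p)))
    return lh.EffectPanel(p=p, t=t, w=w, a=a, h2=0.5, mu_G=float((2 * p * a).sum()))
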