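import numpy as np
import pytest

from granutab.coupling import ModelPair, enumerate_library
from granutab.fitting import (CampaignDataset, FitBudget, FitTemplate, aic,
                              constraint_set_for, fit_pair, r_squared,
                              select_best, sse)

SMALL_BUDGET = FitBudget(de_restarts=1, de_maxiter=60, de_popsize=10,
                         polish_starts=4)

FORCE_TRUTH = [18.50, 0.765, 27.69, 8.73, 0.33, 21.38, 10.0, 2.39, 61.39]


@pytest.fixture(scope="module")
def force_template(geom):
    return FitTemplate(cqa="force", geom=geom)


class TestAic:
    def test_sse_equal_n(self):
        assert aic(10.0, 10, 3) == pytest.approx(6.0)  # ln(1) = 0

    def test_closed_form(self):
        assert aic(10 * np.e**2, 10, 3) == pytest.approx(26.0)

    def test_perfect_fit_warns(self):
        with pytest.warns(RuntimeWarning):
            assert aic(0.0, 5, 2) == -np.inf

    def test_uniform_rescale_shifts_all_equally(self):
        # SSE -> c^2 SSE adds n ln c^2 to every AIC: ordering preserved
        rng = np.random.default_rng(0)
        n = 24
        for _ in range(100):
            sses = rng.uniform(0.01, 50.0, size=6)
            nps = rng.integers(1, 17, size=6)
            c2 = rng.uniform(1e-4, 1e4) ** 2
            a0 = [aic(s, n, k) for s, k in zip(sses, nps)]
            a1 = [aic(c2 * s, n, k) for s, k in zip(sses, nps)]
            assert np.argsort(a0, kind="stable").tolist() == \
                np.argsort(a1, kind="stable").tolist()
            np.testing.assert_allclose(np.array(a1) - np.array(a0),
                                       n * np.log(c2))


class TestRSquared:
    def test_perfect(self):
        e = np.array([1.0, 2.0, 3.0])
        assert r_squared(e, e) == 1.0

    def test_mean_prediction(self):
        e = np.array([1.0, 2.0, 3.0])
        assert r_squared(np.full(3, 2.0), e) == pytest.approx(0.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            r_squared(np.array([1.0, 1.0]), np.array([2.0, 2.0]))


class TestSse:
    def test_truth_on_noiseless_data(self, force_template, noiseless_dataset):
        val = sse(force_template, ModelPair(7, 7), FORCE_TRUTH,
                  noiseless_dataset)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_positive_off_truth(self, force_template, noiseless_dataset):
        theta = list(FORCE_TRUTH)
        theta[-1] *= 1.2  # stiffen the pressure parameter
        assert sse(force_template, ModelPair(7, 7), theta,
                   noiseless_dataset) > 0.01

    def test_infeasible_rejected_as_inf(self, force_template,
                                        noiseless_dataset):
        theta = list(FORCE_TRUTH)
        theta[4] = 0.95  # jamming density above the in-die densities
        assert sse(force_template, ModelPair(7, 7), theta,
                   noiseless_dataset) == np.inf

    def test_recovery_order_constraint_rejected(self, geom,
                                                noiseless_dataset):
        t = FitTemplate(cqa="recovery", geom=geom)
        # p1 > q1 violates the order constraint keeping eps0 in (0, 1)
        theta = [20.0, 0.243, 0.597, 5.0, 16.10, 0.334, 0.472]
        assert sse(t, ModelPair(4, 9), theta, noiseless_dataset) == np.inf


class TestConstraintSets:
    def test_bounds_align_with_layout(self, force_template):
        cs = constraint_set_for(force_template, ModelPair(7, 7))
        assert len(cs.names) == len(cs.bounds) == 9
        assert cs.names[-1] == "b"

    def test_recovery_onset_bounds(self, geom):
        t = FitTemplate(cqa="recovery", geom=geom)
        cs = constraint_set_for(t, ModelPair(4, 9))
        i = cs.names.index("s2_p4")
        lo, hi = cs.bounds[i]
        assert lo == pytest.approx(t.rho_c_lower)
        assert hi < 1.0

    def test_weight_interaction_sign(self, geom):
        t = FitTemplate(cqa="weight", geom=geom)
        cs = constraint_set_for(t, None)
        i = cs.names.index("q1")
        assert cs.bounds[i][1] < 0.0  # q1 strictly negative


class TestFitPair:
    def test_weight_noiseless_recovers_truth(self, geom, noiseless_dataset):
        t = FitTemplate(cqa="weight", geom=geom)
        res = fit_pair(t, None, noiseless_dataset, seed=2)
        assert res.feasible
        assert res.SSE == pytest.approx(0.0, abs=1e-10)
        assert res.theta["p4"] == pytest.approx(0.367, rel=1e-4)
        assert res.theta["q1"] == pytest.approx(-6.08, rel=1e-3)
        assert res.theta["q2"] == pytest.approx(7.33, rel=1e-3)
        assert res.Np == 3

    def test_determinism(self, geom, noiseless_dataset):
        t = FitTemplate(cqa="weight", geom=geom)
        r1 = fit_pair(t, None, noiseless_dataset, seed=9)
        r2 = fit_pair(t, None, noiseless_dataset, seed=9)
        assert r1.theta == r2.theta and r1.SSE == r2.SSE

    def test_aic_recomputable_from_parts(self, geom, noisy_dataset):
        t = FitTemplate(cqa="weight", geom=geom)
        res = fit_pair(t, None, noisy_dataset, seed=2)
        assert res.AIC == pytest.approx(aic(res.SSE, res.n, res.Np))
        assert res.R2 > 0.9

    def test_np_bookkeeping_on_results(self, force_template,
                                       noiseless_dataset):
        res = fit_pair(force_template, ModelPair(9, 9), noiseless_dataset,
                       budget=SMALL_BUDGET, seed=1)
        assert res.Np == 3  # two constants plus b


class TestSelectBest:
    def test_library_of_one(self, geom, noiseless_dataset):
        t = FitTemplate(cqa="recovery", geom=geom)
        out = select_best(t, [ModelPair(9, 9)], noiseless_dataset,
                          budget=SMALL_BUDGET, seed=0)
        assert len(out) == 1 and out[0].pair.astuple() == (9, 9)

    def test_empty_library_rejected(self, geom, noiseless_dataset):
        t = FitTemplate(cqa="recovery", geom=geom)
        with pytest.raises(ValueError):
            select_best(t, [], noiseless_dataset)

    def test_generating_pair_beats_simpler_rivals(self, force_template,
                                                  noisy_dataset):
        """On data generated from a (7,7) force coupling, the generating
        pair outranks constant and simpler alternatives by AIC."""
        sub = [ModelPair(7, 7), ModelPair(8, 8), ModelPair(9, 9),
               ModelPair(4, 9)]
        budget = FitBudget(de_restarts=2, de_maxiter=200, de_popsize=16,
                           polish_starts=8)
        out = select_best(force_template, sub, noisy_dataset,
                          budget=budget, seed=3)
        assert out[0].pair.astuple() == (7, 7)
        assert out[0].AIC < out[-1].AIC

    def test_full_library_enumeration_feeds_selection(self):
        assert len(enumerate_library()) == 25
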