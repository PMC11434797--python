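import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from granutab.coupling import (BelowLowerBoundError, ModelPair,
                               NormalizationOverflowError, NormalizedVariable,
                               RationalSurface, SingularSurfaceError,
                               count_parameters, enumerate_library,
                               eval_surface, limit_profile, normalize,
                               variant_mask)

FIG5 = RationalSurface(variant=1, p1=15, p2=10, p3=5, p4=10,
                       q1=1, q2=2, q3=4)


class TestNormalize:
    def test_lower_bound_maps_to_zero(self):
        v = NormalizedVariable(lb=0.5, ub=1.0, r=3.7)
        assert normalize(0.5, v) == 0.0

    def test_midpoint_maps_to_one(self):
        v = NormalizedVariable(lb=0.2, ub=0.8, r=1.0)
        assert normalize(0.5, v) == pytest.approx(1.0)

    def test_ribbon_density_example(self):
        # high-density ribbon with the force-model exponent
        v = NormalizedVariable(lb=0.566, ub=1.0, r=10.0)
        assert normalize(0.803, v) == pytest.approx((0.237 / 0.197) ** 10,
                                                    rel=1e-12)
        assert normalize(0.803, v) == pytest.approx(6.36, abs=0.01)

    def test_distinct_bound_errors(self):
        v = NormalizedVariable(lb=0.5, ub=1.0)
        with pytest.raises(BelowLowerBoundError):
            normalize(0.4, v)
        with pytest.raises(NormalizationOverflowError):
            normalize(1.0, v)

    @given(st.floats(0.01, 10.0), st.integers(0, 1000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_strictly_increasing(self, r, i):
        v = NormalizedVariable(lb=0.0, ub=1.0, r=r)
        x1 = i / 1001.0
        x2 = x1 + 1e-4
        assert normalize(x2, v) > normalize(x1, v)

    def test_variable_invariants(self):
        with pytest.raises(ValueError):
            NormalizedVariable(lb=1.0, ub=0.5)
        with pytest.raises(ValueError):
            NormalizedVariable(lb=0.0, ub=1.0, r=11.0)


class TestVariantMasks:
    @pytest.mark.parametrize("vid,n_params", [
        (1, 9), (2, 7), (3, 7), (4, 5), (5, 7), (6, 5), (7, 5), (8, 3),
        (9, 1),
    ])
    def test_parameter_counts(self, vid, n_params):
        assert variant_mask(vid).n_parameters == n_params

    def test_variant_8_free_set(self):
        spec = variant_mask(8)
        assert set(spec.free_coeffs) == {"p1", "p4", "q1"}
        assert spec.exponents_fixed
        assert spec.n_free_coeffs == 3

    def test_variant_9_constant(self):
        spec = variant_mask(9)
        assert set(spec.free_coeffs) == {"p4"}

    def test_invalid_id(self):
        with pytest.raises(ValueError):
            variant_mask(10)

    def test_mask_enforced_on_surface(self):
        with pytest.raises(ValueError):
            RationalSurface(variant=7, p1=1.0, p2=0.5, p4=1.0, q1=1.0)


class TestEvalSurface:
    def test_origin_is_p4(self):
        assert eval_surface(FIG5, 0.0, 0.0) == 10.0

    def test_far_corner_is_p1_over_q1(self):
        assert eval_surface(FIG5, math.inf, math.inf) == 15.0

    def test_unit_point(self):
        assert eval_surface(FIG5, 1.0, 1.0) == pytest.approx(5.0)

    def test_mask_eval_commutes_with_zeroing(self):
        # every variant equals the full surface with its coefficients zeroed
        rng = np.random.default_rng(1)
        X, Y = 0.7, 2.3
        for vid in range(1, 10):
            spec = variant_mask(vid)
            coeffs = {c: float(rng.uniform(0.1, 5.0))
                      for c in spec.free_coeffs}
            sv = RationalSurface(variant=vid, **coeffs)
            full = RationalSurface(variant=1, **{c: coeffs.get(c, 0.0)
                                                 for c in
                                                 ("p1", "p2", "p3", "p4",
                                                  "q1", "q2", "q3")})
            assert eval_surface(sv, X, Y) == eval_surface(full, X, Y)

    def test_singular_denominator(self):
        s = RationalSurface(variant=1, p4=1.0, q3=-1.0)
        with pytest.raises(SingularSurfaceError):
            eval_surface(s, 0.0, 1.0)

    def test_array_broadcast(self):
        out = eval_surface(FIG5, np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(out, [10.0, 5.0])


class TestLimitProfiles:
    def test_edge_x_zero(self):
        prof = limit_profile(FIG5, "X=0")
        Y = 3.0
        assert prof(Y) == pytest.approx((5 * Y + 10) / (4 * Y + 1))
        assert prof(0.0) == 10.0  # consistent with the origin corner

    def test_edge_x_inf(self):
        prof = limit_profile(FIG5, "X=inf")
        Y = 2.0
        assert prof(Y) == pytest.approx((15 * Y + 10) / (1 * Y + 2))

    def test_corner_consistency(self):
        # each edge profile reaches the printed corner values
        assert limit_profile(FIG5, "X=0")(math.inf) == pytest.approx(5 / 4)
        assert limit_profile(FIG5, "Y=0")(math.inf) == pytest.approx(10 / 2)
        assert limit_profile(FIG5, "X=inf")(math.inf) == pytest.approx(15 / 1)

    def test_variant_9_constant_on_every_edge(self):
        s = RationalSurface(variant=9, p4=0.334)
        for edge in ("X=0", "X=inf", "Y=0", "Y=inf"):
            prof = limit_profile(s, edge)
            for t in (0.0, 1.0, math.inf):
                assert prof(t) == 0.334

    def test_unknown_edge(self):
        with pytest.raises(ValueError):
            limit_profile(FIG5, "Z=0")


class TestLibrary:
    def test_cardinality(self):
        lib = enumerate_library()
        assert len(lib) == 25
        assert len({p.astuple() for p in lib}) == 25
        assert 9 * 9 == 81  # full pair space it is drawn from

    def test_exact_membership(self):
        tuples = {p.astuple() for p in enumerate_library()}
        expect = ({(v, v) for v in range(1, 9)}
                  | {(v, 9) for v in range(1, 9)}
                  | {(9, w) for w in range(1, 10)})
        assert tuples == expect
        assert (7, 7) in tuples and (7, 3) not in tuples

    @pytest.mark.parametrize("pair,n_constants,np_expect", [
        ((7, 7), 1, 9),    # compaction-force pair plus b
        ((4, 9), 1, 7),    # recovery pair plus n
        ((1, 1), 0, 16),   # tensile-strength pair
        ((9, 9), 1, 3),    # two constants plus one scalar
        ((8, 8), 1, 7),
    ])
    def test_parameter_bookkeeping(self, pair, n_constants, np_expect):
        assert count_parameters(ModelPair(*pair), n_constants) == np_expect

    def test_exponents_shared_and_fixed_only_when_both_fix(self):
        assert ModelPair(4, 9).exponents_fixed
        assert not ModelPair(7, 9).exponents_fixed
        assert not ModelPair(1, 1).exponents_fixed

    def test_count_rejects_non_library_pair(self):
        with pytest.raises(ValueError):
            count_parameters(ModelPair(7, 3), 1)

    def test_serialization_round_trip(self):
        s = RationalSurface(variant=7, p1=18.5, p4=0.765, q1=27.69)
        assert RationalSurface.from_dict(s.to_dict()) == s
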