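import numpy as np
import pytest

from granutab.coupling import RationalSurface, eval_surface
from granutab.geometry import PressSetpoints, fill_volume
from granutab.gsd import BimodalWeibull, GranuleBatch
from granutab.roms import (BrouwersReference, CoupledROM, InfeasibleStateError,
                           KawakitaParams, NoCoherentTabletError,
                           PackingParams, RecoveryParams, StrengthParams,
                           brouwers_packing, compaction_force,
                           elastic_recovery, evaluate_coupled,
                           out_of_die_density, packing_fraction,
                           tablet_weight, tensile_strength)

KP = KawakitaParams(a=0.765, b=61.39e-3, rho_c=0.33)  # b in 1/MPa
RP = RecoveryParams(eps0=0.597, rho_c_eps=0.334, n_exp=0.472)
SP = StrengthParams(sigma0=5.90, rho_c_sigma=0.51)
PP = PackingParams(p4=0.367, q1=-6.08, q2=7.33)


class TestCompactionForce:
    def test_zero_at_jamming_onset(self, geom):
        assert compaction_force(KP.rho_c, KP, geom) == 0.0

    def test_worked_example(self, geom):
        f = compaction_force(0.85, KP, geom)
        assert f == pytest.approx(3.22, abs=0.01)

    def test_strictly_increasing_in_density(self, geom):
        rho = np.linspace(0.35, 0.95, 50)
        f = compaction_force(rho, KP, geom)
        assert np.all(np.diff(f) > 0)

    def test_infeasible_state_signal(self, geom):
        with pytest.raises(InfeasibleStateError):
            compaction_force(0.30, KP, geom)  # below jamming


class TestElasticRecovery:
    def test_zero_at_onset(self):
        assert elastic_recovery(RP.rho_c_eps, RP) == 0.0

    def test_full_compaction_gives_eps0(self):
        assert elastic_recovery(1.0, RP) == pytest.approx(RP.eps0)

    def test_worked_example(self):
        assert elastic_recovery(0.85, RP) == pytest.approx(0.529, abs=1e-3)

    def test_below_onset_clamps_to_zero(self):
        assert elastic_recovery(0.2, RP) == 0.0


class TestOutOfDieDensity:
    def test_no_recovery_identity(self):
        assert out_of_die_density(0.83, 0.0) == 0.83

    def test_product_form(self):
        assert out_of_die_density(0.9, 0.1) == pytest.approx(0.81)

    def test_composed_density_below_in_die(self):
        rho = np.linspace(0.4, 0.99, 30)
        eps = elastic_recovery(rho, RP)
        rho_tab = out_of_die_density(rho, eps)
        assert np.all(rho_tab[rho > RP.rho_c_eps] < rho[rho > RP.rho_c_eps])

    def test_rejects_invalid_recovery(self):
        with pytest.raises(ValueError):
            out_of_die_density(0.9, 1.0)


class TestTensileStrength:
    def test_zero_at_threshold(self):
        assert tensile_strength(SP.rho_c_sigma, SP) == pytest.approx(0.0)

    def test_sigma0_at_full_density(self):
        assert tensile_strength(1.0, SP) == pytest.approx(SP.sigma0)

    def test_worked_example(self):
        assert tensile_strength(0.85, SP) == pytest.approx(3.36, abs=0.01)

    def test_no_coherent_tablet_signal(self):
        with pytest.raises(NoCoherentTabletError):
            tensile_strength(0.40, SP)


class TestPackingFraction:
    def test_unimodal_large_mode(self):
        for X in (0.0, 0.3, 0.8):
            assert packing_fraction(X, 0.0, PP) == pytest.approx(PP.p4)

    def test_equal_mode_sizes(self):
        assert packing_fraction(0.0, 0.7, PP) == pytest.approx(PP.p4)

    def test_worked_example(self):
        assert packing_fraction(0.3, 0.7, PP) == pytest.approx(0.611,
                                                               abs=1e-3)

    def test_at_least_unimodal_on_unit_square(self):
        X, Y = np.meshgrid(np.linspace(0, 1, 21), np.linspace(0, 1, 21))
        phi = packing_fraction(X, Y, PP)
        assert np.all(phi >= PP.p4 - 1e-12)

    def test_implied_p2_constraint(self):
        assert PP.p2 == pytest.approx(PP.q2 * PP.p4)


class TestTabletWeight:
    def test_arithmetic(self, geom, ref):
        # unimodal GSD so phi = p4; near-solid ribbon
        gsd = BimodalWeibull(0.0, 400, 700, 2.0, 5.0)
        batch = GranuleBatch(ribbon_density=0.999, gsd=gsd)
        vf = fill_volume(geom, 8.0)
        w = tablet_weight(batch, PP, geom, 8.0, 1.558)
        assert w == pytest.approx(0.367 * 1.558 * 0.999 * vf, rel=1e-12)

    def test_linear_in_fill_volume(self, geom, batches):
        w1 = tablet_weight(batches[0], PP, geom, 4.0, 1.558)
        w2 = tablet_weight(batches[0], PP, geom, 8.0, 1.558)
        vf1, vf2 = fill_volume(geom, 4.0), fill_volume(geom, 8.0)
        assert w2 / w1 == pytest.approx(vf2 / vf1)

    def test_increasing_in_ribbon_density(self, geom, batches):
        gsd = batches[0].gsd
        ws = [tablet_weight(GranuleBatch(r, gsd), PP, geom, 8.0, 1.558)
              for r in (0.6, 0.7, 0.8, 0.9)]
        assert np.all(np.diff(ws) > 0)


class TestBrouwersReference:
    REF = BrouwersReference(phi_rp=0.64, C=0.2)

    def test_monodisperse_limit(self):
        assert brouwers_packing(1.0, 0.4, self.REF) == pytest.approx(0.64)

    def test_zero_constant_collapses(self):
        ref0 = BrouwersReference(phi_rp=0.64, C=0.0)
        for u, a in [(0.3, 0.2), (0.7, 0.9), (1.0, 0.5)]:
            assert brouwers_packing(u, a, ref0) == pytest.approx(0.64)

    def test_exceeds_random_packing(self):
        u, a = np.meshgrid(np.linspace(0.2, 1.0, 15), np.linspace(0, 1, 15))
        phi = brouwers_packing(u, a, self.REF)
        assert np.all(phi >= self.REF.phi_rp - 1e-12)


class TestCoupledROM:
    def test_force_parameters_at_dense_batch(self, ref, batches, geom):
        # 90 bar / 2 mm granules: the stiffest, least compressible batch
        a, rho_c = ref.rom("force", geom).xi(batches[4])
        assert a == pytest.approx(0.668, abs=2e-3)
        assert 0.33 < rho_c < 0.45

    def test_low_density_limit_is_corner_value(self, ref, geom, batches):
        batch = GranuleBatch(ribbon_density=0.5661, gsd=batches[0].gsd)
        a, rho_c = ref.rom("force", geom).xi(batch)
        assert a == pytest.approx(0.765, abs=1e-3)
        assert rho_c == pytest.approx(0.33, abs=1e-3)

    def test_recovery_onset_constant_across_batches(self, ref, batches, geom):
        rom = ref.rom("recovery", geom)
        for b in batches:
            assert rom.xi(b)[1] == 0.334

    def test_kawakita_a_range_and_trend(self, ref, batches, geom):
        rom = ref.rom("force", geom)
        a_vals = [rom.xi(b)[0] for b in batches]
        assert all(0.66 <= a <= 0.77 for a in a_vals)
        # at fixed GSD, compressibility falls as the ribbon densifies
        gsd = batches[2].gsd
        a_sweep = [rom.xi(GranuleBatch(r, gsd))[0]
                   for r in np.linspace(0.60, 0.85, 8)]
        assert np.all(np.diff(a_sweep) <= 1e-12)
        assert a_sweep[-1] < a_sweep[0]

    def test_constant_pair_reproduces_uncoupled_rom(self, geom, batches):
        rom = CoupledROM(
            cqa="force", geom=geom,
            surface1=RationalSurface(variant=9, p4=KP.a),
            surface2=RationalSurface(variant=9, p4=KP.rho_c),
            constant=61.39)
        press = PressSetpoints(t_fill=8.0, t_pc=5.0, t_in_die=3.0)
        w = 250.0
        got = evaluate_coupled(rom, batches[0], press, W=w)
        from granutab.geometry import compact_volume
        rho = w / (1.558 * compact_volume(geom, 3.0))
        assert got == pytest.approx(compaction_force(rho, KP, geom),
                                    rel=1e-12)

    def test_weight_and_strength_chain(self, ref, batches, geom):
        roms = ref.rom_set(geom)
        press = PressSetpoints(t_fill=8.0, t_pc=5.0, t_in_die=3.5)
        w = evaluate_coupled(roms["weight"], batches[4], press)
        rho_tab = evaluate_coupled(roms["recovery"], batches[4], press, W=w)
        sigma = evaluate_coupled(roms["strength"], batches[4], press,
                                 rho_tablet=rho_tab)
        assert w > 0 and 0 < rho_tab < 1 and sigma > 0

    def test_out_of_range_ribbon_rejected(self, ref, batches, geom):
        rom = ref.rom("force", geom)
        bad = GranuleBatch(ribbon_density=0.50, gsd=batches[0].gsd)
        press = PressSetpoints(t_fill=8.0, t_pc=5.0, t_in_die=3.0)
        with pytest.raises(InfeasibleStateError):
            evaluate_coupled(rom, bad, press, W=250.0)
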