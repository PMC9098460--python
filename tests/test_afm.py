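"""Hertz forward model, contact-point detection and modulus fitting."""

import numpy as np
import pytest

from nucleomech import synthetic as syn
from nucleomech.afm import (ForceCurve, HertzFitConfig, find_contact_point,
                            fit_hertz, hertz_force, read_force_curve,
                            summarize_moduli)
from _oracles import hertz_force_scalar


class TestForwardModel:
    def test_zero_depth_zero_force(self):
        assert hertz_force(0.0, 1000.0) == 0.0

    def test_reference_point_against_independent_evaluation(self):
        # E = 10 kPa, nu = 0.5, R = 5 µm, delta = 0.5 µm -> ~1.406e-8 N
        f = hertz_force(0.5e-6, 1e4, 0.5, 5e-6)
        assert f == pytest.approx(1.406e-8, rel=1e-3)
        assert f == pytest.approx(
            hertz_force_scalar(0.5e-6, 1e4, 0.5, 5e-6), rel=1e-12)

    def test_three_halves_power_law(self, rng):
        for _ in range(20):
            E = rng.uniform(100, 1e5)
            R = rng.uniform(1e-6, 2e-5)
            d = rng.uniform(1e-8, 1e-6)
            assert hertz_force(2 * d, E, 0.5, R) / hertz_force(d, E, 0.5, R) \
                == pytest.approx(2 ** 1.5, rel=1e-12)

    def test_negative_depth_returns_zero(self):
        assert np.all(hertz_force(np.array([-1e-7, -1e-9]), 1000.0) == 0.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            hertz_force(1e-7, -5.0)
        with pytest.raises(ValueError):
            hertz_force(1e-7, 1000.0, nu=1.5)


class TestContactPoint:
    def test_contact_shift_recovered_within_one_sample(self):
        spec = syn.SyntheticCurveSpec(E_true=1000.0, contact_shift=0.2e-6)
        curve = syn.simulate_force_curve(spec)
        d0, baseline = find_contact_point(curve)
        assert d0 == pytest.approx(0.2e-6, abs=curve.sample_spacing)
        assert baseline == pytest.approx(0.0, abs=1e-15)

    def test_pure_baseline_curve_raises(self):
        d = np.linspace(-5e-7, 5e-7, 100)
        with pytest.raises(ValueError, match="no contact"):
            find_contact_point(ForceCurve(d, np.full(100, 2e-10)))

    def test_force_offset_moves_baseline_not_contact(self):
        spec = syn.SyntheticCurveSpec(E_true=1000.0)
        c0 = syn.simulate_force_curve(spec)
        c1 = ForceCurve(c0.delta, c0.force + 3e-10)
        d0a, b0 = find_contact_point(c0)
        d0b, b1 = find_contact_point(c1)
        assert d0b == pytest.approx(d0a, abs=1e-12)
        assert b1 - b0 == pytest.approx(3e-10, abs=1e-15)


class TestFitHertz:
    def test_noiseless_round_trip_exact(self):
        curve = syn.simulate_force_curve(syn.SyntheticCurveSpec(E_true=5000.0))
        res = fit_hertz(curve)
        assert res.converged
        assert res.E == pytest.approx(5000.0, rel=1e-6)

    def test_noisy_median_recovery_within_ten_percent(self):
        E = 1000.0
        noiseless = syn.simulate_force_curve(syn.SyntheticCurveSpec(E_true=E))
        sd = 0.02 * float(noiseless.force.max())
        fitted = [fit_hertz(syn.simulate_force_curve(
            syn.SyntheticCurveSpec(E_true=E, noise_sd=sd, seed=s))).E
            for s in range(50)]
        assert np.median(fitted) == pytest.approx(E, rel=0.10)

    def test_depth_gate_limits_points_used(self):
        # ramp far beyond the gate: only gated samples enter the fit
        spec = syn.SyntheticCurveSpec(E_true=200.0, delta_max=3.0e-6,
                                      n_points=1200, force_stop=None)
        curve = syn.simulate_force_curve(spec)
        res = fit_hertz(curve)
        in_gate = (curve.delta - res.contact_point > 0) \
            & (curve.delta - res.contact_point <= res.depth_gate) \
            & (curve.force - res.baseline <= res.force_gate)
        assert res.n_points_used == int(in_gate.sum())
        assert res.n_points_used < len(curve)

    def test_gates_never_violated(self):
        for s in range(5):
            spec = syn.SyntheticCurveSpec(E_true=3000.0, noise_sd=2e-11,
                                          seed=s)
            curve = syn.simulate_force_curve(spec)
            res = fit_hertz(curve)
            d = curve.delta - res.contact_point
            f = curve.force - res.baseline
            used = (d > 0) & (d <= res.depth_gate) & (f <= res.force_gate)
            assert used.sum() == res.n_points_used

    def test_force_scaling_equivariance(self):
        curve = syn.simulate_force_curve(syn.SyntheticCurveSpec(E_true=800.0))
        res1 = fit_hertz(curve)
        c = 1.7
        res2 = fit_hertz(ForceCurve(curve.delta, curve.force * c),
                         cfg=HertzFitConfig(force_gate=c * 2e-9))
        assert res2.E == pytest.approx(c * res1.E, rel=1e-5)

    def test_radius_scaling_equivariance(self):
        curve = syn.simulate_force_curve(syn.SyntheticCurveSpec(E_true=800.0))
        res1 = fit_hertz(curve, R=5e-6)
        res4 = fit_hertz(curve, R=4 * 5e-6)
        assert res4.E == pytest.approx(res1.E / 2.0, rel=1e-5)

    def test_too_few_gated_points_raises(self):
        spec = syn.SyntheticCurveSpec(E_true=1000.0, n_points=30)
        curve = syn.simulate_force_curve(spec)
        with pytest.raises(ValueError, match="sample"):
            fit_hertz(curve, cfg=HertzFitConfig(min_points=500))


class TestSummaryAndIO:
    def _result(self, E, cond="a", ok=True):
        from nucleomech.afm import HertzFitResult
        return HertzFitResult(E, 0.5, 5e-6, 0.0, 0.0, 50, 0.0, ok,
                              0.5e-6, 2e-9, condition=cond)

    def test_median_of_three(self):
        df = summarize_moduli([self._result(e) for e in (1000, 2000, 3000)])
        assert df.loc[0, "median_Pa"] == 2000.0

    def test_single_fit_quartiles_collapse(self):
        df = summarize_moduli([self._result(1500.0)])
        assert df.loc[0, "q1_Pa"] == df.loc[0, "q3_Pa"] == 1500.0

    def test_nonconverged_excluded_and_counted(self):
        df = summarize_moduli([self._result(1000.0),
                               self._result(9000.0, ok=False)])
        assert df.loc[0, "n"] == 1 and df.loc[0, "n_excluded"] == 1

    def test_doubled_modulus_between_conditions(self):
        fits = []
        for s in range(12):
            for cond, E in (("soft", 800.0), ("stiff", 1600.0)):
                c = syn.simulate_force_curve(
                    syn.SyntheticCurveSpec(E_true=E, noise_sd=5e-12, seed=s),
                    condition=cond)
                fits.append(fit_hertz(c))
        df = summarize_moduli(fits).set_index("condition")
        assert df.loc["stiff", "median_Pa"] / df.loc["soft", "median_Pa"] \
            == pytest.approx(2.0, abs=0.3)

    def test_curve_text_round_trip_units(self, tmp_path):
        curve = syn.simulate_force_curve(syn.SyntheticCurveSpec(E_true=900.0))
        p = tmp_path / "c.csv"
        p.write_text("delta_um,force_nN\n" + "\n".join(
            f"{d * 1e6},{f * 1e9}" for d, f in zip(curve.delta, curve.force)))
        back = read_force_curve(p)
        assert np.allclose(back.delta, curve.delta)
        assert np.allclose(back.force, curve.force)

    def test_raw_mode_conversion(self, tmp_path):
        z = np.linspace(0, 1e-6, 50)
        defl = np.linspace(0, 2e-8, 50)
        p = tmp_path / "raw.txt"
        p.write_text("# k = 0.05 N/m\nz_m\tdeflection_m\taux\n" + "\n".join(
            f"{a}\t{b}\t0" for a, b in zip(z, defl)))
        curve = read_force_curve(p)
        assert np.allclose(curve.force, 0.05 * defl)
        assert np.allclose(curve.delta, z - defl)
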