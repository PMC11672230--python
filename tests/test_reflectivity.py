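"""Forward-model checks: Fresnel oracle, invariances, smearing, I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adlayer as al
from adlayer.layers import LayerStack, Slab, Substrate
from adlayer.reflectivity import model_curve, smear_function


def bare_interface(backing_sld, fronting_sld=2.07e-6, roughness=0.0):
    protein = al.get_protein("COE3")
    sub = Substrate(
        fronting_sld=fronting_sld, oxide_thickness=0.0, oxide_roughness=roughness
    )
    return LayerStack(substrate=sub, slabs=[], protein=protein)


def fresnel(q, rho0, rho1, sigma=0.0):
    k0 = q / 2.0
    k1 = np.sqrt((q / 2.0) ** 2 - 4 * np.pi * (rho1 - rho0) + 0j)
    k1 = np.where(k1.imag < 0, -k1, k1)
    r = (k0 - k1) / (k0 + k1) * np.exp(-2 * k0 * k1 * sigma**2)
    return np.abs(r) ** 2


class TestQKinematics:
    def test_q_from_angle_formula(self):
        assert al.q_from_angle(1.0, 6.0) == pytest.approx(
            4 * math.pi * math.sin(math.radians(1.0)) / 6.0
        )
        assert al.q_from_angle(90.0 - 1e-9, 4 * math.pi) == pytest.approx(1.0)

    def test_q_small_angle_limit(self):
        assert al.q_from_angle(1e-6, 6.0) == pytest.approx(0.0, abs=1e-7)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            al.q_from_angle(-1.0, 6.0)
        with pytest.raises(ValueError):
            al.q_from_angle(1.0, 0.0)

    def test_critical_q(self):
        assert al.critical_q(0.0) == 0.0
        assert al.critical_q(-1e-6) == 0.0
        assert al.critical_q(4.28e-6) == pytest.approx(4 * math.sqrt(math.pi * 4.28e-6))
        assert al.critical_q(2 * 4.28e-6) == pytest.approx(
            math.sqrt(2) * al.critical_q(4.28e-6)
        )


class TestAbelesOracles:
    q = np.linspace(0.005, 0.3, 400)

    def test_no_contrast_gives_zero(self):
        stack = bare_interface(backing_sld=None, fronting_sld=2.07e-6)
        solvent = al.ContrastSolvent("match", 2.07e-6)
        curve = al.abeles_reflectivity(stack, solvent, self.q)
        assert np.all(curve.r < 1e-20)

    def test_fresnel_limit_exact(self):
        stack = bare_interface(6.35e-6)
        curve = al.abeles_reflectivity(stack, al.D2O, self.q)
        expected = fresnel(self.q, 2.07e-6, 6.35e-6)
        assert np.max(np.abs(curve.r - expected) / expected) < 1e-10

    def test_fresnel_limit_with_roughness(self):
        stack = bare_interface(6.35e-6, roughness=4.0)
        curve = al.abeles_reflectivity(stack, al.D2O, self.q)
        expected = fresnel(self.q, 2.07e-6, 6.35e-6, sigma=4.0)
        above = self.q > 1.1 * al.critical_q(4.28e-6)
        assert np.allclose(curve.r[above], expected[above], rtol=1e-9)

    def test_total_reflection_below_critical_edge(self):
        stack = bare_interface(6.35e-6)
        qc = al.critical_q(6.35e-6 - 2.07e-6)
        q = np.linspace(0.2 * qc, 0.95 * qc, 50)
        curve = al.abeles_reflectivity(stack, al.D2O, q)
        assert np.allclose(curve.r, 1.0, atol=1e-12)

    def test_invisible_layer(self, stack_ph55):
        q = self.q
        base = al.abeles_reflectivity(stack_ph55, al.D2O, q)
        # a slab with phi=0 has solvent SLD: optically invisible
        padded = LayerStack(
            substrate=stack_ph55.substrate,
            slabs=stack_ph55.slabs + [Slab(37.0, 0.0)],
            protein=stack_ph55.protein,
        )
        curve = al.abeles_reflectivity(padded, al.D2O, q)
        assert np.max(np.abs(curve.r - base.r)) < 1e-10

    def test_slab_splitting_invariance(self, coe3):
        q = self.q
        sub = Substrate()
        whole = LayerStack(sub, [Slab(50.0, 0.4)], coe3)
        split = LayerStack(sub, [Slab(25.0, 0.4), Slab(25.0, 0.4)], coe3)
        r1 = al.abeles_reflectivity(whole, al.D2O, q).r
        r2 = al.abeles_reflectivity(split, al.D2O, q).r
        assert np.max(np.abs(r1 - r2)) < 1e-10

    def test_empty_q_rejected(self, stack_ph55):
        with pytest.raises(ValueError):
            al.abeles_reflectivity(stack_ph55, al.D2O, np.array([]))

    @given(
        tau1=st.floats(5.0, 100.0),
        tau2=st.floats(5.0, 100.0),
        phi1=st.floats(0.0, 0.7),
        phi2=st.floats(0.0, 0.7),
        sigma=st.floats(0.0, 8.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_energy_bound(self, tau1, tau2, phi1, phi2, sigma):
        """Unscaled model reflectivity stays in [0, 1] for arbitrary stacks."""
        protein = al.get_protein("COE3")
        stack = LayerStack(
            Substrate(oxide_roughness=sigma),
            [Slab(tau1, phi1, sigma), Slab(tau2, phi2)],
            protein,
        )
        for contrast in (al.D2O, al.H2O):
            r = al.abeles_reflectivity(stack, contrast, self.q).r
            assert np.all(r >= 0.0) and np.all(r <= 1.0 + 1e-12)

    @pytest.mark.parametrize("tau", [60.0, 70.0, 80.0])
    def test_kinematic_fringe_spacing(self, tau, coe3):
        """Thickness fringes at large Q have spacing ~2*pi/tau (within 2%)."""
        stack = LayerStack(
            Substrate(oxide_thickness=0.0, oxide_roughness=0.0),
            [Slab(tau, 0.5)],
            coe3,
        )
        q = np.linspace(0.05, 0.30, 6000)
        r = al.abeles_reflectivity(stack, al.D2O, q).r
        # minima of R*q^4 locate the destructive-interference fringes
        rq4 = r * q**4
        idx = [
            i
            for i in range(1, len(q) - 1)
            if rq4[i] < rq4[i - 1] and rq4[i] < rq4[i + 1]
        ]
        spacings = np.diff(q[idx])
        assert np.mean(spacings) == pytest.approx(2 * np.pi / tau, rel=0.02)


class TestSmearing:
    def test_zero_resolution_is_identity(self, stack_ph55):
        q = np.linspace(0.01, 0.2, 100)
        base = al.abeles_reflectivity(stack_ph55, al.D2O, q)
        assert np.array_equal(al.smear(base, 0.0).r, base.r)

    def test_constant_curve_unchanged(self):
        q = np.linspace(0.01, 0.2, 50)
        r = smear_function(q, lambda qq: np.full_like(qq, 0.37), 0.05)
        assert np.allclose(r, 0.37, rtol=1e-12)

    def test_smeared_edge_monotone_and_matches_quadrature(self):
        q = np.linspace(0.005, 0.05, 120)

        def model(qq):
            # closed-form Fresnel edge: monotone, defined on any grid
            return fresnel(np.atleast_1d(np.asarray(qq, dtype=float)), 2.07e-6, 6.35e-6)

        r_sm = smear_function(q, model, 0.04)
        assert np.all(np.diff(r_sm) <= 1e-12)  # edge stays monotone
        # brute-force Gaussian quadrature oracle at a few points
        from scipy.integrate import quad

        fwhm = 2 * math.sqrt(2 * math.log(2))
        for q_near in (0.012, 0.02, 0.04):
            qi = float(q[np.argmin(np.abs(q - q_near))])
            sig = 0.04 * qi / fwhm
            val, _ = quad(
                lambda u: model(np.array([qi + u]))[0]
                * math.exp(-0.5 * (u / sig) ** 2)
                / (sig * math.sqrt(2 * math.pi)),
                -3.5 * sig,
                3.5 * sig,
            )
            idx = int(np.argmin(np.abs(q - qi)))
            assert r_sm[idx] == pytest.approx(val, rel=0.01)


class TestInstrument:
    def test_identity(self):
        q = np.linspace(0.01, 0.1, 20)
        c = al.ReflectivityCurve(q=q, r=np.exp(-q * 30))
        out = al.apply_instrument(c, al.InstrumentModel(scale=1.0, background=0.0))
        assert np.array_equal(out.r, c.r)

    def test_scale_and_background(self):
        q = np.linspace(0.01, 0.1, 20)
        c = al.ReflectivityCurve(q=q, r=np.exp(-q * 30))
        out = al.apply_instrument(c, al.InstrumentModel(scale=2.0, background=1e-6))
        assert np.allclose(out.r, 2.0 * c.r + 1e-6)
        assert out.r.min() >= 1e-6

    def test_invalid_instrument(self):
        with pytest.raises(ValueError):
            al.InstrumentModel(scale=0.0)
        with pytest.raises(ValueError):
            al.InstrumentModel(dq_over_q=0.5)


class TestAsciiIO:
    def test_round_trip(self, tmp_path, stack_ph55):
        q = np.linspace(0.01, 0.2, 40)
        curve = al.abeles_reflectivity(stack_ph55, al.CM4, q)
        curve.dr = 0.02 * curve.r
        curve.dq = 0.04 * q
        p = tmp_path / "curve.dat"
        al.write_curve(p, curve, header={"contrast": "CM4"})
        back = al.read_curve(p)
        assert np.allclose(back.q, curve.q)
        assert np.allclose(back.r, curve.r, rtol=1e-6)
        assert np.allclose(back.dr, curve.dr, rtol=1e-6)
        assert np.allclose(back.dq, curve.dq, rtol=1e-6)

    def test_reads_comma_delimited_two_column(self, tmp_path):
        p = tmp_path / "two.dat"
        p.write_text("# q, r\n0.01, 0.9\n0.02, 0.5\n")
        c = al.read_curve(p)
        assert c.dr is None and len(c.q) == 2

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.dat"
        p.write_text("# only a header\n")
        with pytest.raises(ValueError):
            al.read_curve(p)

    def test_decreasing_q_rejected(self, tmp_path):
        p = tmp_path / "bad.dat"
        p.write_text("0.02 0.5\n0.01 0.9\n")
        with pytest.raises(ValueError):
            al.read_curve(p)
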