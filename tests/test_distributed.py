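"""Closed-form PSD transfer functions vs quadrature and Riemann sums."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cablepsd import (
    DEFAULT_PARAMS,
    InputEnsembleSpec,
    closed_form_integrals,
    compose_total_psd,
    psd_transfer,
    relative_input_density,
    riemann_sum_psd,
)
from cablepsd.params import dimensionless_map

from test_single_input import make_point

MODALITIES = ("soma_current", "dipole", "soma_potential")


def quad_complex(fn, a, b):
    re = quad(lambda x: fn(x).real, a, b, limit=300)[0]
    im = quad(lambda x: fn(x).imag, a, b, limit=300)[0]
    return re + 1j * im


class TestClosedFormIntegrals:
    @given(
        W=st.floats(min_value=0.0, max_value=500.0),
        L=st.floats(min_value=0.05, max_value=4.0),
    )
    @settings(max_examples=20, deadline=None)
    def test_match_adaptive_quadrature(self, W, L):
        point = make_point(W, L, 0.2)
        q = point.q
        vals = closed_form_integrals(point)
        oracle = {
            "I1": quad_complex(lambda X: abs(np.cosh(q * (L - X))) ** 2 + 0j, 0, L),
            "I2": quad_complex(lambda X: abs(np.cosh(q * X)) ** 2 + 0j, 0, L),
            "I3": quad_complex(lambda X: abs(np.sinh(q * X)) ** 2 + 0j, 0, L),
            "I4": quad_complex(
                lambda X: np.cosh(q * (L - X)) * np.cosh(np.conj(q) * X), 0, L
            ),
            "I5": quad_complex(
                lambda X: np.cosh(q * (L - X)) * np.sinh(np.conj(q) * X), 0, L
            ),
            "I6": quad_complex(
                lambda X: np.cosh(q * X) * np.sinh(np.conj(q) * X), 0, L
            ),
        }
        scale = abs(oracle["I1"])  # natural magnitude of the set
        for name, expect in oracle.items():
            got = getattr(vals, name)
            assert abs(got - expect) <= 1e-9 * max(scale, abs(expect)), name

    def test_real_at_dc_and_complex_off_dc(self):
        dc = closed_form_integrals(make_point(0.0, 1.0, 0.2))
        assert dc.I5.imag == pytest.approx(0.0, abs=1e-15)
        assert dc.I6.imag == pytest.approx(0.0, abs=1e-15)
        ac = closed_form_integrals(make_point(10.0, 1.0, 0.2))
        assert abs(ac.I5.imag) > 0 and abs(ac.I6.imag) > 0
        for name in ("I1", "I2", "I3", "I4"):
            assert isinstance(getattr(ac, name), float)

    def test_vanishing_domain(self):
        vals = closed_form_integrals(make_point(5.0, 1e-9, 0.2))
        for name in ("I1", "I2", "I3", "I4", "I5", "I6"):
            assert abs(getattr(vals, name)) < 1e-8


class TestComponents:
    def test_correlated_homogeneous_kills_current_and_dipole(self, params):
        ens = InputEnsembleSpec(n_d=2e12, n_s=2e12, coherence=1.0)
        f = np.logspace(-1, 4, 30)
        for modality in ("soma_current", "dipole"):
            tr = psd_transfer(params, f, modality, ens)
            assert np.all(tr.T_corr == 0.0)

    def test_correlated_homogeneous_soma_potential_is_lorentzian(self, params):
        ens = InputEnsembleSpec(n_d=2e12, n_s=2e12, coherence=1.0)
        f = np.logspace(-1, 4, 50)
        W = 2 * np.pi * f * 0.03
        tr = psd_transfer(params, f, "soma_potential", ens)
        # T = (n/G_m)^2/(1 + W^2): iso-potential single-compartment neuron
        expect = (2e12 / params.membrane_conductance) ** 2 / (1 + W**2)
        np.testing.assert_allclose(tr.T_corr, expect, rtol=1e-12)

    def test_component_nonnegativity_random_sample(self, rng):
        for _ in range(12):
            W = 10 ** rng.uniform(-2, 6)
            L = 10 ** rng.uniform(-0.7, 0.6)
            b = 10 ** rng.uniform(-2, 1)
            from cablepsd.slopes import transfer_curve

            for modality in MODALITIES:
                for cls in ("unc_dend", "unc_soma", "corr", "corr_dend"):
                    val = transfer_curve(np.array([W]), modality, cls, L=L, b=b,
                                         rho=0.3)[0]
                    assert val >= 0.0

    def test_density_scaling_linear_and_quadratic(self, params):
        f = np.array([10.0, 300.0])
        base = InputEnsembleSpec(n_d=1e12, n_s=2e12, coherence=0.0)
        doubled = InputEnsembleSpec(n_d=2e12, n_s=4e12, coherence=0.0)
        for modality in MODALITIES:
            t1 = psd_transfer(params, f, modality, base)
            t2 = psd_transfer(params, f, modality, doubled)
            np.testing.assert_allclose(t2.T_unc_dend, 2 * t1.T_unc_dend, rtol=1e-12)
            np.testing.assert_allclose(t2.T_unc_soma, 2 * t1.T_unc_soma, rtol=1e-12)
            np.testing.assert_allclose(t2.T_corr, 4 * t1.T_corr, rtol=1e-12)


class TestComposition:
    def test_dendrite_only_uncorrelated(self, params):
        ens = InputEnsembleSpec(n_d=2e12, n_s=0.0, coherence=0.0, input_psd=1e-30)
        f = np.logspace(0, 3, 10)
        tr = psd_transfer(params, f, "soma_current", ens)
        np.testing.assert_allclose(
            compose_total_psd(tr, ens), 1e-30 * tr.T_unc_dend, rtol=1e-14
        )
        assert np.all(tr.T_unc_soma == 0.0)

    def test_pink_input_adds_one_to_slope_everywhere(self, params):
        from cablepsd import local_slope

        f = np.logspace(-1, 3, 120)
        white = InputEnsembleSpec(n_d=2e12, n_s=2e12, coherence=0.0, input_psd=1.0)
        pink = InputEnsembleSpec(
            n_d=2e12, n_s=2e12, coherence=0.0,
            input_psd=lambda ff: 1.0 / np.asarray(ff),
        )
        tr = psd_transfer(params, f, "soma_potential", white)
        mu_w = local_slope(f, compose_total_psd(tr, white)).mu
        mu_p = local_slope(f, compose_total_psd(tr, pink)).mu
        np.testing.assert_allclose(mu_p, mu_w + 1.0, atol=1e-9)

    def test_coherence_validation(self, params):
        with pytest.raises(ValueError, match="coherence"):
            InputEnsembleSpec(n_d=1.0, n_s=1.0, coherence=1.5)
        ens = InputEnsembleSpec(
            n_d=1.0, n_s=1.0, coherence=lambda f: np.full_like(f, 2.0)
        )
        tr = psd_transfer(params, np.logspace(0, 1, 5), "dipole", ens)
        with pytest.raises(ValueError, match="coherence"):
            compose_total_psd(tr, ens)

    def test_rho_definition(self):
        assert relative_input_density(2.0, 2.0) == 0.5
        assert relative_input_density(0.0, 2.0) == 0.0
        assert relative_input_density(2.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            relative_input_density(0.0, 0.0)

    def test_corr_continuity_as_rho_to_zero(self, params):
        """Mixed-density correlated V converges to the dendrite-only case."""
        f = np.logspace(0, 3, 12)
        t0 = psd_transfer(
            params, f, "soma_potential",
            InputEnsembleSpec(n_d=2e12, n_s=0.0, coherence=1.0),
        ).T_corr
        for eps in (1e-3, 1e-5):
            t = psd_transfer(
                params, f, "soma_potential",
                InputEnsembleSpec(n_d=2e12, n_s=2e12 * eps, coherence=1.0),
            ).T_corr
            np.testing.assert_allclose(t, t0, rtol=50 * eps)


class TestRiemannSum:
    @pytest.mark.parametrize("modality", MODALITIES)
    def test_paper_resolution_agreement(self, params, modality, white_ensemble):
        """200 dendritic segments agree with closed forms at f <= 1 kHz."""
        ens = InputEnsembleSpec(n_d=2e12, n_s=2e12, coherence=0.5)
        for f0 in (1.0, 100.0, 1000.0):
            tr = psd_transfer(params, [f0], modality, ens)
            rs = riemann_sum_psd(params, f0, modality, 200, ens)
            assert rs["unc_dend"] == pytest.approx(tr.T_unc_dend[0], rel=1e-2)
            if tr.T_corr[0] > 0:
                assert rs["corr"] == pytest.approx(tr.T_corr[0], rel=1e-2)

    def test_10k_segments_within_0p1_percent(self, params, rng):
        for _ in range(4):
            W = 10 ** rng.uniform(-1, 4)
            f0 = W / (2 * np.pi * 0.03)
            modality = MODALITIES[rng.integers(0, 3)]
            ens = InputEnsembleSpec(n_d=1e12, n_s=3e12, coherence=0.5)
            tr = psd_transfer(params, [f0], modality, ens)
            rs = riemann_sum_psd(params, f0, modality, 10_000, ens)
            assert rs["unc_dend"] == pytest.approx(tr.T_unc_dend[0], rel=1e-3)
            assert rs["corr"] == pytest.approx(tr.T_corr[0], rel=1e-3)

    def test_single_segment_reduces_to_midpoint_transfer(self, params):
        from cablepsd import transfer_single

        ens = InputEnsembleSpec(n_d=2e12, n_s=0.0, coherence=0.0)
        f0 = 50.0
        point = dimensionless_map(params, f0)
        rs = riemann_sum_psd(params, f0, "soma_potential", 1, ens)
        h = transfer_single(point, point.L / 2, "soma_potential").value
        weight = 2e12 * np.pi * params.stick_diameter * point.length_constant * point.L
        assert rs["unc_dend"] == pytest.approx(weight * abs(h) ** 2, rel=1e-12)

    def test_error_decreases_when_n_doubles(self, params):
        ens = InputEnsembleSpec(n_d=2e12, n_s=0.0, coherence=0.0)
        tr = psd_transfer(params, [200.0], "dipole", ens).T_unc_dend[0]
        errs = [
            abs(riemann_sum_psd(params, 200.0, "dipole", n, ens)["unc_dend"] - tr) / tr
            for n in (50, 100, 200, 400)
        ]
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))
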