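import numpy as np
import pytest

from conftest import random_omegas
from dendrogap.closed_forms import (
    TwoCellInfiniteConfig,
    passive_F,
    passive_infinite_G,
    passive_rect_response,
    passive_two_cell_G,
    two_cell_ghat,
    word_series_ghat,
)
from dendrogap.fixtures import (
    resonant_dendrite,
    two_cell_identical_config,
    two_soma_config,
)
from dendrogap.kernels import ghat_infinite
from dendrogap.transforms import Stimulus, inverse_laplace, voltage_response
from scipy.special import erfc


class TestTwoCellFrequencyDomain:
    def test_junction_point_superposition(self, identical_cfg):
        """At x = 0 the same-cell and cross-cell responses sum to the free
        infinite-cable kernel (the coupling terms cancel)."""
        w = random_omegas(31, 20)
        p = identical_cfg.params_m
        total = two_cell_ghat(identical_cfg, "m-", 0.0, 100.0, w) + two_cell_ghat(
            identical_cfg, "n-", 0.0, 100.0, w
        )
        assert np.allclose(total, ghat_infinite(p, 100.0, w) / p.c_len, rtol=1e-12)

    def test_decoupling_limit(self):
        cfg = two_cell_identical_config(R_GJ=1e12)
        w = random_omegas(32, 10)
        p = cfg.params_m
        assert np.allclose(
            two_cell_ghat(cfg, "m-", 10.0, 100.0, w),
            ghat_infinite(p, 90.0, w) / p.c_len,
            rtol=1e-8,
        )
        cross = np.abs(two_cell_ghat(cfg, "n-", 10.0, 100.0, w))
        same = np.abs(two_cell_ghat(cfg, "m-", 10.0, 100.0, w))
        assert np.max(cross / same) < 1e-9

    def test_heterogeneous_reduces_to_identical(self, identical_cfg):
        p = identical_cfg.params_m
        hetero_equal = TwoCellInfiniteConfig(params_m=p, params_n=p, R_GJ=100.0)
        w = random_omegas(33, 20)
        for seg in ("m-", "m+", "n-"):
            assert np.allclose(
                two_cell_ghat(hetero_equal, seg, 17.0, 130.0, w),
                two_cell_ghat(identical_cfg, seg, 17.0, 130.0, w),
                rtol=1e-12,
            )


class TestWordSeries:
    @pytest.mark.parametrize("cell", [1, 2])
    def test_soma_observation_merges_brackets(self, soma_cfg, cell):
        """x0 = 0: both bracket terms merge with weight 2 p_s, giving the
        somatic response series (written out independently here)."""
        w = random_omegas(34, 10)
        ps = soma_cfg.p_s(w)
        pgj = soma_cfg.p_gj(w)
        p = soma_cfg.params
        L, y0 = soma_cfg.L_GJ, soma_cfg.y0
        lead = pgj if cell == 2 else 1 - pgj
        sgn = 2 * pgj - 1 if cell == 2 else 1 - 2 * pgj
        expected = 2 * ps * lead * ghat_infinite(p, y0, w)
        for n in range(0, 4):
            expected = expected + (
                2**n
                * (-pgj * (2 * ps - 1)) ** (n + 1)
                * sgn
                * 2
                * ps
                * ghat_infinite(p, y0 + 2 * (n + 1) * L, w)
            )
        got = word_series_ghat(soma_cfg, cell, 0.0, w, n_max=3)
        assert np.allclose(got, expected / p.c_len, rtol=1e-12)

    def test_perfect_coupling_symmetrises_cells(self):
        cfg = two_soma_config(L_GJ=100.0, R_GJ=1e-9)
        w = random_omegas(35, 10)
        g1 = word_series_ghat(cfg, 1, 0.0, w, n_max=20)
        g2 = word_series_ghat(cfg, 2, 0.0, w, n_max=20)
        p = cfg.params
        expected = cfg.p_s(w) * ghat_infinite(p, cfg.y0, w) / p.c_len
        assert np.allclose(g1, g2, rtol=1e-8)
        assert np.allclose(g1, expected, rtol=1e-8)

    @pytest.mark.parametrize("soma_resonant,dendrites_resonant",
                             [(False, True), (True, False), (True, True)])
    def test_rapid_convergence(self, soma_resonant, dendrites_resonant):
        """Truncation at 10 vs 20 terms differs by < 1e-6 relative."""
        cfg = two_soma_config(
            L_GJ=150.0, soma_resonant=soma_resonant, dendrites_resonant=dendrites_resonant
        )
        w = np.linspace(0.01, 5.0, 200) + 0.0j
        for cell in (1, 2):
            g10 = word_series_ghat(cfg, cell, 0.0, w, n_max=10)
            g20 = word_series_ghat(cfg, cell, 0.0, w, n_max=20)
            assert np.max(np.abs(g10 / g20 - 1)) < 1e-6


class TestPassiveTimeDomain:
    def test_F_vanishes_before_onset(self, pas_params):
        t = np.array([-1.0, 0.0, 1.0])
        vals = passive_F(110.0, t, 0.01, pas_params)
        assert vals[0] == 0.0 and vals[1] == 0.0 and vals[2] > 0

    def test_F_zero_rate_reduction(self, pas_params):
        """q = 0: F = 1/2 e^{-t/tau} erfc(|x|/(2 sqrt(D t)))."""
        t = np.array([1.0, 5.0, 20.0])
        D, tau = pas_params.D, pas_params.tau
        expected = 0.5 * np.exp(-t / tau) * erfc(110.0 / (2 * np.sqrt(D * t)))
        assert np.allclose(passive_F(110.0, t, 0.0, pas_params), expected, rtol=1e-12)

    def test_F_matches_numerical_inversion(self, pas_params):
        q = pas_params.ra / 100.0
        t = np.array([1.0, 5.0, 20.0])

        def fhat(w):
            return ghat_infinite(pas_params, 110.0, w) / (
                __import__("dendrogap.kernels", fromlist=["gamma"]).gamma(pas_params, w) + q
            )

        got = inverse_laplace(fhat, t, tolerance=1e-7)
        assert np.allclose(got, passive_F(110.0, t, q, pas_params), rtol=1e-6)

    def test_segment_sum_identity(self, pas_params):
        """G_m- + G_n+- = G_inf(x - y, t)/c at all (x, y, t)."""
        t = np.linspace(0.1, 50.0, 40)
        total = passive_two_cell_G("m-", 10.0, 100.0, t, pas_params, 100.0) + passive_two_cell_G(
            "n-", 10.0, 100.0, t, pas_params, 100.0
        )
        free = passive_infinite_G(10.0 - 100.0, t, pas_params) / pas_params.c_len
        assert np.allclose(total, free, rtol=1e-12, atol=1e-300)

    def test_cross_cell_response_vanishes_at_early_times(self, pas_params):
        t = np.array([1e-6, 1e-4])
        vals = passive_two_cell_G("n-", 10.0, 100.0, t, pas_params, 100.0)
        assert np.all(vals < 1e-30)

    def test_rect_segment_sum_identity(self, pas_params):
        """V_m- + V_n+- = [B(x-y,t) - B(x-y,t-tauR)]/c (coupling terms
        cancel)."""
        t = np.linspace(0.5, 30.0, 30)
        vm = passive_rect_response("m-", 10.0, 100.0, t, pas_params, 100.0, 2.0, 5.0)
        vn = passive_rect_response("n-", 10.0, 100.0, t, pas_params, 100.0, 2.0, 5.0)
        from dendrogap.closed_forms import _rect_B_diff

        free = _rect_B_diff(10.0 - 100.0, t, 2.0, 5.0, pas_params) / pas_params.c_len
        assert np.allclose(vm + vn, free, rtol=1e-10)

    def test_rect_response_zero_before_onset(self, pas_params):
        t = np.array([-5.0, -0.1])
        for seg in ("m-", "m+", "n-"):
            assert np.all(
                passive_rect_response(seg, 10.0, 100.0, t, pas_params, 100.0, 2.0, 5.0) == 0.0
            )

    def test_rect_matches_numerical_pipeline(self, passive_cfg, pas_params):
        t = np.array([0.5, 2.0, 5.0, 8.0, 15.0, 30.0])
        stim = Stimulus("rectangular", eta0=2.0, tau_R=5.0)
        for seg in ("m-", "n-"):
            ghat = lambda w, s=seg: two_cell_ghat(passive_cfg, s, 10.0, 100.0, w)
            got = voltage_response(ghat, stim, t, tolerance=1e-6)
            want = passive_rect_response(seg, 10.0, 100.0, t, pas_params, 100.0, 2.0, 5.0)
            assert np.allclose(got, want, rtol=1e-5)

    def test_degenerate_coupling_raises(self, pas_params):
        r_deg = pas_params.ra * np.sqrt(pas_params.D * pas_params.tau)
        with pytest.raises(Exception, match="perturb"):
            passive_rect_response(
                "n-", 10.0, 100.0, np.array([1.0]), pas_params, float(r_deg), 2.0, 5.0
            )
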