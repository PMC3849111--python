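import numpy as np
import pytest

from conftest import TWO_CELL_SEGMENTS, random_omegas
from dendrogap.closed_forms import two_cell_ghat, word_series_ghat
from dendrogap.fixtures import (
    resonant_dendrite,
    two_cell_identical_config,
    two_cell_network_config,
    two_soma_config,
    two_soma_network_config,
)
from dendrogap.kernels import FrequencyKernelSet
from dendrogap.network_model import NetworkError, PointLocation, build_network
from dendrogap.trips_engine import (
    GreensEvaluator,
    enumerate_trips,
    greens_laplace,
    scaled_trip_length,
    trip_coefficient,
)


class TestEnumeration:
    def test_same_segment_has_direct_and_reflected_trip(self, identical_net):
        ex = enumerate_trips(
            identical_net,
            PointLocation("cell_m:minus", 10.0),
            PointLocation("cell_m:minus", 100.0),
            cutoff=1000.0,
        )
        assert ex.exhausted  # the trip set is finite
        assert [t.total_length for t in ex.trips] == [90.0, 110.0]
        assert ex.trips[0].factors == ()
        assert [e[1] for e in ex.trips[1].events] == ["gj_reflect"]

    def test_cross_cell_single_trip(self, identical_net):
        ex = enumerate_trips(
            identical_net,
            PointLocation("cell_n:minus", 10.0),
            PointLocation("cell_m:minus", 100.0),
            cutoff=1000.0,
        )
        assert len(ex.trips) == 1
        assert ex.trips[0].total_length == 110.0
        assert [e[1] for e in ex.trips[0].events] == ["gj_cross"]

    def test_cutoff_below_shortest_trip_raises(self, identical_net):
        with pytest.raises(NetworkError, match="empty"):
            enumerate_trips(
                identical_net,
                PointLocation("cell_n:minus", 10.0),
                PointLocation("cell_m:minus", 100.0),
                cutoff=50.0,
            )

    def test_trips_sorted_and_unique(self, soma_net):
        ex = enumerate_trips(
            soma_net,
            PointLocation("cell2:gjdend", 0.0),
            PointLocation("cell1:gjdend", 110.0),
            cutoff=1500.0,
        )
        lengths = [t.total_length for t in ex.trips]
        assert lengths == sorted(lengths)
        keys = [(t.events, round(t.total_length, 9)) for t in ex.trips]
        assert len(set(keys)) == len(keys)

    def test_soma_reflection_then_crossing_coefficient(self, soma_cfg, soma_net):
        """The trip soma-reflect -> junction-cross carries (2 p_s - 1) p_GJ."""
        ex = enumerate_trips(
            soma_net,
            PointLocation("cell2:gjdend", 0.0),
            PointLocation("cell1:gjdend", 110.0),
            cutoff=115.0,
        )
        # two trips of scaled length y0 - x0: direct cross, and
        # soma-reflected (zero-length first leg) then cross
        assert len(ex.trips) == 2
        w = random_omegas(3, 4)
        kern = FrequencyKernelSet(soma_net, w)
        a0 = trip_coefficient(ex.trips[0], kern)
        a1 = trip_coefficient(ex.trips[1], kern)
        pgj = soma_cfg.p_gj(w)
        ps = soma_cfg.p_s(w)
        got = sorted([a0, a1], key=lambda a: abs(a[0]))
        want = sorted([pgj, (2 * ps - 1) * pgj], key=lambda a: abs(a[0]))
        assert np.allclose(got[0], want[0], rtol=1e-12)
        assert np.allclose(got[1], want[1], rtol=1e-12)


class TestScaledLength:
    def test_homogeneous_scaling(self, identical_net):
        ex = enumerate_trips(
            identical_net,
            PointLocation("cell_m:minus", 10.0),
            PointLocation("cell_m:minus", 100.0),
            cutoff=1000.0,
        )
        w = np.array([0.4 + 0.1j])
        kern = FrequencyKernelSet(identical_net, w)
        g = kern.gamma_of("cell_m:minus")
        for t in ex.trips:
            assert scaled_trip_length(t, kern) == pytest.approx(g[0] * t.total_length)

    def test_heterogeneous_mixed_exponent(self, hetero_net, hetero_cfg):
        """A trip crossing the junction accumulates gamma_n x + gamma_m y."""
        ex = enumerate_trips(
            hetero_net,
            PointLocation("cell_n:minus", 10.0),
            PointLocation("cell_m:minus", 100.0),
            cutoff=500.0,
        )
        w = np.array([0.8 - 0.3j])
        kern = FrequencyKernelSet(hetero_net, w)
        gm = kern.gamma_of("cell_m:minus")
        gn = kern.gamma_of("cell_n:minus")
        assert scaled_trip_length(ex.trips[0], kern) == pytest.approx(gn[0] * 10 + gm[0] * 100)


class TestGreensLaplace:
    @pytest.mark.parametrize("segment", list(TWO_CELL_SEGMENTS))
    def test_matches_identical_closed_form(self, identical_net, identical_cfg, segment):
        w = random_omegas(21, 20)
        got = greens_laplace(
            identical_net,
            PointLocation(TWO_CELL_SEGMENTS[segment], 10.0),
            PointLocation("cell_m:minus", 100.0),
            w,
        )
        want = two_cell_ghat(identical_cfg, segment, 10.0, 100.0, w)
        assert np.allclose(got, want, rtol=1e-12)

    @pytest.mark.parametrize("segment", list(TWO_CELL_SEGMENTS))
    def test_matches_heterogeneous_closed_form(self, hetero_net, hetero_cfg, segment):
        w = random_omegas(22, 20)
        got = greens_laplace(
            hetero_net,
            PointLocation(TWO_CELL_SEGMENTS[segment], 10.0),
            PointLocation("cell_m:minus", 100.0),
            w,
        )
        want = two_cell_ghat(hetero_cfg, segment, 10.0, 100.0, w)
        assert np.allclose(got, want, rtol=1e-12)

    def test_matches_word_series_off_soma(self):
        """Observation between soma and junction (x0 > 0)."""
        cfg = two_soma_config(L_GJ=200.0, R_GJ=100.0)
        net = build_network(two_soma_network_config(cfg))
        w = random_omegas(23, 10, re=(0.1, 2.0), im=(-1.0, 1.0))
        got = greens_laplace(
            net,
            PointLocation("cell2:gjdend", 120.0),
            PointLocation("cell1:gjdend", 210.0),
            w,
            tol=1e-11,
        )
        want = word_series_ghat(cfg, 2, 120.0, w, n_max=30)
        assert np.allclose(got, want, rtol=1e-8)

    def test_reciprocity_on_homogeneous_network(self, soma_net):
        w = random_omegas(24, 6)
        x = PointLocation("cell1:gjdend", 30.0)
        y = PointLocation("cell1:gjdend", 150.0)
        fwd = greens_laplace(soma_net, x, y, w, tol=1e-11)
        rev = greens_laplace(soma_net, y, x, w, tol=1e-11)
        assert np.allclose(fwd, rev, rtol=1e-8)

    def test_node_observation_matches_both_segment_conventions(self):
        """x exactly at the junction: both incident-segment assignments
        agree (value continuity)."""
        cfg = two_soma_config(L_GJ=200.0, R_GJ=100.0)
        net = build_network(two_soma_network_config(cfg))
        w = random_omegas(25, 5, re=(0.2, 2.0), im=(-1.0, 1.0))
        y = PointLocation("cell1:gjdend", 250.0)
        a = greens_laplace(net, PointLocation("cell2:gjdend.prox", 200.0), y, w, tol=1e-10)
        b = greens_laplace(net, PointLocation("cell2:gjdend.dist", 0.0), y, w, tol=1e-10)
        assert np.allclose(a, b, rtol=1e-8)

    def test_decoupled_limit_matches_free_cable(self):
        from dendrogap.closed_forms import TwoCellInfiniteConfig, two_cell_ghat
        from dendrogap.kernels import ghat_infinite

        p = resonant_dendrite()
        cfg = TwoCellInfiniteConfig(params_m=p, params_n=p, R_GJ=1e9)
        net = build_network(two_cell_network_config(cfg))
        w = random_omegas(26, 8)
        same = greens_laplace(
            net, PointLocation("cell_m:minus", 10.0), PointLocation("cell_m:minus", 100.0), w
        )
        cross = greens_laplace(
            net, PointLocation("cell_n:minus", 10.0), PointLocation("cell_m:minus", 100.0), w
        )
        free = ghat_infinite(p, 90.0, w) / p.c_len
        # cross-coupling shrinks like p_GJ ~ 1/(2 z R_GJ) and tracks the
        # closed form exactly
        assert np.max(np.abs(cross / same)) < 1e-7
        assert np.allclose(cross, two_cell_ghat(cfg, "n-", 10.0, 100.0, w), rtol=1e-12)
        assert np.allclose(same, free, rtol=1e-6)

    def test_shell_contributions_decay(self, soma_net):
        """Length-shell contributions decay geometrically once trips exceed
        a few decay lengths."""
        ev = GreensEvaluator(
            soma_net,
            PointLocation("cell1:gjdend", 0.0),
            PointLocation("cell1:gjdend", 110.0),
        )
        w = np.array([0.3 + 0.0j])
        kern = FrequencyKernelSet(soma_net, w)
        width = ev._shell_width(kern)
        ev._extend_to(6 * width)
        mags = []
        for k in range(5):
            shell = [
                t for t in ev._trips if k * width < t.total_length <= (k + 1) * width
            ]
            s_p, s_m = ev._bulk_shell(shell, kern)
            mags.append(float(np.abs(s_p + s_m)[0]))
        mags = [m for m in mags if m > 0]
        assert all(b < 0.7 * a for a, b in zip(mags[1:], mags[2:]))
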