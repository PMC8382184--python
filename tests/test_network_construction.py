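"""PLV pipeline: filtering, phases, surrogates, and edge-pruning stages."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.fft import rfft

from ictonet.model import WeightedNetwork
from ictonet.networks import (
    NetworkConfig,
    ROITimeSeriesSet,
    build_network,
    iaaft_surrogate,
    indirect_path_filter,
    instantaneous_phase,
    plv_matrix,
    plv_pair,
    surrogate_mask,
    theta_bandpass,
    zero_lag_mask,
    zero_lag_threshold,
)


def _sine_set(freqs, fs=1000.0, duration=4.0, phases=None, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(fs * duration)) / fs
    phases = phases or [0.0] * len(freqs)
    data = np.array(
        [np.cos(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)]
    )
    if noise:
        data = data + noise * rng.standard_normal(data.shape)
    return ROITimeSeriesSet(data, fs)


class TestBandpass:
    def test_passband_and_stopband(self):
        ts = _sine_set([6.0, 20.0])
        out = theta_bandpass(ts)
        mid = slice(1000, 3000)  # avoid filter edge transients
        assert np.ptp(out.data[0, mid]) / np.ptp(ts.data[0, mid]) >= 0.95
        assert np.ptp(out.data[1, mid]) / np.ptp(ts.data[1, mid]) <= 0.1

    def test_zero_in_zero_out(self):
        ts = ROITimeSeriesSet(np.zeros((2, 1000)), 1000.0)
        assert np.allclose(theta_bandpass(ts).data, 0.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            theta_bandpass(ROITimeSeriesSet(np.random.default_rng(0).random((1, 64)), 10.0))


class TestInstantaneousPhase:
    def test_phase_slope_matches_frequency(self):
        ts = _sine_set([6.0])
        phi = np.unwrap(instantaneous_phase(ts)[0, 200:-200])
        slope = np.polyfit(np.arange(phi.size) / ts.fs, phi, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 6.0, rel=0.005)

    def test_cos_vs_sin_quarter_cycle(self):
        # sin lags cos by pi/2
        ts = _sine_set([6.0, 6.0], phases=[0.0, -np.pi / 2])
        phi = instantaneous_phase(ts)
        dphi = np.angle(np.exp(1j * (phi[0, 500:-500] - phi[1, 500:-500])))
        assert np.abs(dphi.mean() - np.pi / 2) < 0.01

    def test_channel_permutation_permutes_phases(self):
        ts = _sine_set([5.0, 6.0, 7.0], noise=0.1)
        phi = instantaneous_phase(ts)
        perm = [2, 0, 1]
        phi_p = instantaneous_phase(ROITimeSeriesSet(ts.data[perm], ts.fs))
        assert np.allclose(phi[perm], phi_p)

    def test_constant_channel_rejected(self):
        data = np.vstack([np.ones(1000), np.random.default_rng(0).random(1000)])
        with pytest.raises(ValueError, match="constant"):
            instantaneous_phase(ROITimeSeriesSet(data, 1000.0))


class TestPLV:
    def test_identical_series(self):
        phi = np.random.default_rng(0).uniform(-np.pi, np.pi, 500)
        plv, dphi = plv_pair(phi, phi)
        assert plv == pytest.approx(1.0)
        assert dphi == pytest.approx(0.0)

    def test_constant_offset(self):
        phi = np.linspace(0, 40 * np.pi, 800)
        plv, dphi = plv_pair(phi + np.pi / 2, phi)
        assert plv == pytest.approx(1.0)
        assert dphi == pytest.approx(np.pi / 2)

    def test_independent_phases_give_low_plv(self):
        rng = np.random.default_rng(1)
        low = [
            plv_pair(rng.uniform(0, 2 * np.pi, 1000), rng.uniform(0, 2 * np.pi, 1000))[0]
            for _ in range(50)
        ]
        # resultant length of n random unit vectors ~ 1/sqrt(n); 0.1 is ~3 sigma
        assert np.mean(np.array(low) < 0.1) > 0.9

    def test_matrix_matches_pairwise_definition(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(-np.pi, np.pi, (4, 300))
        plv, dphi = plv_matrix(phases)
        for a, b in itertools.combinations(range(4), 2):
            p, d = plv_pair(phases[a], phases[b])
            assert plv[a, b] == pytest.approx(p, abs=1e-12)
            assert dphi[a, b] == pytest.approx(d, abs=1e-12)

    def test_global_phase_shift_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 2 * np.pi, (2, 400))
        assert plv_pair(a, b)[0] == pytest.approx(plv_pair(a + 1.23, b + 1.23)[0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            plv_pair(np.zeros(10), np.zeros(11))

    @given(
        arrays(np.float64, 64, elements=st.floats(-50, 50)),
        arrays(np.float64, 64, elements=st.floats(-50, 50)),
    )
    @settings(max_examples=50, deadline=None)
    def test_plv_always_in_unit_interval(self, a, b):
        plv, dphi = plv_pair(a, b)
        assert 0.0 <= plv <= 1.0 + 1e-12
        assert -np.pi <= dphi <= np.pi


class TestIAAFT:
    def test_amplitude_distribution_exact(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        s = iaaft_surrogate(x, seed=1)
        assert np.array_equal(np.sort(s), np.sort(x))

    def test_spectrum_approximately_preserved(self):
        rng = np.random.default_rng(0)
        t = np.arange(20_000) / 1000.0
        x = np.cos(2 * np.pi * 6 * t) + 0.5 * rng.standard_normal(t.size)
        s = iaaft_surrogate(x, seed=2)
        ax, asur = np.abs(rfft(x)), np.abs(rfft(s))
        rel_err = np.linalg.norm(asur - ax) / np.linalg.norm(ax)
        assert rel_err < 0.05

    def test_seeds_give_distinct_surrogates(self):
        x = np.random.default_rng(0).standard_normal(256)
        assert not np.array_equal(iaaft_surrogate(x, seed=1), iaaft_surrogate(x, seed=2))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            iaaft_surrogate(np.ones(64))


class TestZeroLagMask:
    def test_printed_threshold(self):
        # one-sample phase resolution at 4 Hz / 1 kHz = 0.008*pi radians
        assert zero_lag_threshold(1000.0, 4.0) == pytest.approx(0.008 * np.pi)

    @pytest.mark.parametrize(
        "dphi,fs,kept",
        [
            (0.0, 1000.0, False),
            (0.008 * np.pi, 1000.0, True),  # boundary: strict "less than" rejects
            (np.pi / 2, 1000.0, True),
            (-0.005 * np.pi, 1000.0, False),
        ],
    )
    def test_boundary_behavior(self, dphi, fs, kept):
        assert zero_lag_mask(np.array([[dphi]]), fs)[0, 0] == kept


def _brute_force_path_filter(net: WeightedNetwork) -> np.ndarray:
    """Oracle: enumerate all simple paths; drop edges with a strictly shorter
    alternative path."""
    import networkx as nx

    g = nx.Graph()
    n = net.n
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if net.weights[i, j] > 0:
                g.add_edge(i, j, length=1.0 / net.weights[i, j])
    keep = net.weights.copy()
    for i, j in list(g.edges):
        direct = g[i][j]["length"]
        best = min(
            (
                sum(g[a][b]["length"] for a, b in zip(path, path[1:]))
                for path in nx.all_simple_paths(g, i, j)
                if len(path) > 2
            ),
            default=np.inf,
        )
        if best < direct * (1 - 1e-12):
            keep[i, j] = keep[j, i] = 0.0
    return keep


class TestIndirectPathFilter:
    def test_triangle_weak_edge_removed(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.9
        w[0, 2] = w[2, 0] = 0.4  # direct length 2.5 > 1/0.9 + 1/0.9 = 2.22
        out = indirect_path_filter(WeightedNetwork(w))
        assert out.weights[0, 2] == 0.0
        assert out.weights[0, 1] == 0.9 and out.weights[1, 2] == 0.9

    def test_single_edge_kept(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.3
        assert indirect_path_filter(WeightedNetwork(w)).weights[0, 1] == 0.3

    def test_equilateral_triangle_all_kept(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0.0)
        out = indirect_path_filter(WeightedNetwork(w))
        assert np.array_equal(out.weights, w)

    def test_idempotent_and_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(3, 7))
            w = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            mask = rng.random(len(iu[0])) < 0.6
            w[iu] = np.where(mask, rng.uniform(0.1, 1.0, len(iu[0])), 0.0)
            net = WeightedNetwork(w + w.T)
            once = indirect_path_filter(net)
            assert np.array_equal(once.weights, _brute_force_path_filter(net))
            twice = indirect_path_filter(once)
            assert np.array_equal(once.weights, twice.weights)


class TestSurrogateMask:
    def test_locked_edge_retained(self):
        rng = np.random.default_rng(4)
        t = np.arange(5_000) / 1000.0
        base = np.cos(2 * np.pi * 6 * t + 0.4 * np.sin(2 * np.pi * 0.3 * t))
        data = np.vstack([base + 0.2 * rng.standard_normal(t.size),
                          np.roll(base, 15) + 0.2 * rng.standard_normal(t.size)])
        ts = ROITimeSeriesSet(data, 1000.0)
        cfg = NetworkConfig(n_surrogates=19, trim=0.5, seed=0)
        from ictonet.networks import _pipeline_phases

        phases = _pipeline_phases(ts.data, ts.fs, cfg)
        mask = surrogate_mask(phases, ts, n_surr=19, seed=0, config=cfg)
        assert mask[0, 1]

    def test_null_calibration(self):
        """Independent white-noise channels: retention rate ~ alpha."""
        rng = np.random.default_rng(5)
        ts = ROITimeSeriesSet(rng.standard_normal((12, 3_000)), 250.0)
        cfg = NetworkConfig(n_surrogates=19, trim=0.5, seed=1)
        from ictonet.networks import _pipeline_phases

        phases = _pipeline_phases(ts.data, ts.fs, cfg)
        mask = surrogate_mask(phases, ts, n_surr=19, seed=1, config=cfg)
        iu = np.triu_indices(12, 1)
        rate = mask[iu].mean()
        # 66 edges at alpha=0.05: binomial 99.9% upper bound ~ 0.15
        assert rate < 0.16

    def test_insufficient_surrogates_rejected(self):
        with pytest.raises(ValueError):
            surrogate_mask(np.zeros((2, 100)), ROITimeSeriesSet(np.zeros((2, 100)), 100.0), n_surr=5)


@pytest.fixture(scope="module")
def planted():
    from ictonet.synth import make_topology, simulate_roi_signals

    net = make_topology(8, "modular", seed=10)
    ts = simulate_roi_signals(net, fs=250, duration=12, seed=11)
    cfg = NetworkConfig(n_surrogates=19, seed=12)
    return net, build_network(ts, cfg)


class TestBuildNetwork:

    def test_structural_contract(self, planted):
        _, fn = planted
        w = fn.final.weights
        assert np.array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert np.all((w >= 0) & (w <= 1))

    def test_masks_only_remove(self, planted):
        _, fn = planted
        support = fn.final.weights > 0
        surr_zero = fn.plv * fn.masks["surrogate"] * fn.masks["zero_lag"]
        assert np.all(support <= (surr_zero > 0))
        assert np.all(support <= fn.masks["path"] | ~support)

    def test_planted_structure_recovered(self, planted):
        net, fn = planted
        iu = np.triu_indices(net.n, 1)
        edge = net.weights[iu] > 0
        kept = fn.final.weights[iu] > 0
        assert kept[edge].mean() > kept[~edge].mean()

    def test_identical_copies_yield_empty_network(self):
        rng = np.random.default_rng(13)
        t = np.arange(2_000) / 250.0
        sig = np.cos(2 * np.pi * 6 * t) + 0.3 * rng.standard_normal(t.size)
        data = np.tile(sig, (5, 1))
        fn = build_network(
            ROITimeSeriesSet(data, 250.0), NetworkConfig(n_surrogates=19, trim=0.5, seed=14)
        )
        assert np.all(fn.final.weights == 0)
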