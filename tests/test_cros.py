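"""CROS simulator: topology, dynamics contracts, parameter sampling."""

import numpy as np
import pytest

from neurofei.cros import (
    NetworkConfig,
    build_network,
    network_signal,
    run_simulation,
    sample_diagonal,
    sample_phase_space,
)


class TestBuildNetwork:
    def test_same_seed_same_topology(self):
        cfg = NetworkConfig(grid_side=20, seed=5)
        n1, n2 = build_network(cfg), build_network(cfg)
        np.testing.assert_array_equal(n1.indices, n2.indices)
        np.testing.assert_array_equal(n1.excitatory, n2.excitatory)

    def test_different_seeds_differ(self):
        n1 = build_network(NetworkConfig(grid_side=20, seed=1))
        n2 = build_network(NetworkConfig(grid_side=20, seed=2))
        assert n1.indices.size != n2.indices.size or not np.array_equal(
            n1.indices, n2.indices
        )

    def test_excitatory_fraction(self):
        net = build_network(NetworkConfig(seed=0))
        assert net.excitatory.sum() == round(0.75 * 2500)

    def test_zero_connectivity_means_no_edges(self):
        net = build_network(NetworkConfig(grid_side=15, c_e=0.0, c_i=0.0, seed=0))
        assert net.indices.size == 0

    def test_mean_out_degree_matches_connectivity_percentage(self):
        # excitatory sources reach C_E% of the local excitatory candidates
        cfg = NetworkConfig(c_e=36.0, c_i=44.0, seed=0)
        ratios = []
        for seed in range(30):
            net = build_network(NetworkConfig(c_e=36.0, c_i=44.0, seed=seed))
            g = cfg.grid_side
            exc_grid = net.excitatory.reshape(g, g)
            # count local excitatory candidates per excitatory source
            deg_to_e = net.out_degree(to_excitatory=True)
            n_cand = np.zeros(cfg.n_neurons)
            reach = cfg.local_range_e
            for row in range(g):
                for col in range(g):
                    block = exc_grid[
                        max(0, row - reach): row + reach + 1,
                        max(0, col - reach): col + reach + 1,
                    ]
                    j = row * g + col
                    n_cand[j] = block.sum() - exc_grid[row, col]
            src = net.excitatory & (n_cand > 0)
            ratios.append((deg_to_e[src] / n_cand[src]).mean())
        assert np.mean(ratios) == pytest.approx(0.36, abs=0.01)

    def test_weights_signed_by_source_type(self):
        net = build_network(NetworkConfig(grid_side=15, seed=3))
        src = np.repeat(net.excitatory, np.diff(net.indptr))
        assert np.all(net.weights[src] > 0)
        assert np.all(net.weights[~src] < 0)


class TestRunSimulation:
    def test_fixed_seed_is_bitwise_reproducible(self):
        cfg = NetworkConfig(grid_side=15, seed=7)
        net = build_network(cfg)
        r1 = run_simulation(net, 5.0)
        r2 = run_simulation(net, 5.0)
        np.testing.assert_array_equal(r1.counts, r2.counts)

    def test_raster_length_and_bounds(self, tiny_cros_raster):
        assert tiny_cros_raster.counts.size == int(20.0 * 1000)
        assert tiny_cros_raster.counts.min() >= 0
        assert tiny_cros_raster.counts.max() <= 400  # n_neurons of 20x20 grid

    def test_disconnected_network_fires_at_spontaneous_rate(self):
        cfg = NetworkConfig(
            grid_side=20, c_e=0.0, c_i=0.0, p_spont=0.01,
            refractory_ms=0.0, seed=1,
        )
        raster = run_simulation(build_network(cfg), 20.0)
        rate = raster.counts.mean() / cfg.n_neurons
        assert rate == pytest.approx(0.01, rel=0.05)

    def test_excitation_raises_activity_and_alpha_power(self):
        from neurofei.bands import FrequencyBin, band_envelope
        from neurofei.timeseries import TimeSeries

        low = NetworkConfig(c_e=31.0, c_i=49.0, seed=2)
        high = NetworkConfig(c_e=41.0, c_i=39.0, seed=2)
        r_low = run_simulation(build_network(low), 60.0)
        r_high = run_simulation(build_network(high), 60.0)
        assert r_high.counts.mean() > r_low.counts.mean()
        alpha = FrequencyBin(8.0, 10.5, 4)
        p = []
        for r in (r_low, r_high):
            ts = TimeSeries(network_signal(r, seed=9), r.fs)
            p.append(np.mean(band_envelope(ts, alpha).envelope ** 2))
        assert p[1] > p[0]

    def test_mismatched_fs_rejected(self, tiny_cros_raster):
        net = build_network(NetworkConfig(grid_side=10, seed=0))
        with pytest.raises(ValueError, match="timestep"):
            run_simulation(net, 1.0, fs=500.0)


class TestNetworkSignal:
    def test_zero_noise_returns_counts(self, tiny_cros_raster):
        sig = network_signal(tiny_cros_raster, noise_sd=0.0)
        np.testing.assert_array_equal(sig, tiny_cros_raster.counts)

    def test_default_noise_variance_on_silent_raster(self):
        from neurofei.cros import SpikeRaster

        raster = SpikeRaster(counts=np.zeros(200_000, dtype=int), fs=1000.0)
        sig = network_signal(raster, noise_sd=3.0, seed=0)
        assert sig.mean() == pytest.approx(0.0, abs=0.05)
        assert sig.var() == pytest.approx(9.0, rel=0.02)

    def test_same_raster_different_noise_seeds(self, tiny_cros_raster):
        s1 = network_signal(tiny_cros_raster, seed=1)
        s2 = network_signal(tiny_cros_raster, seed=2)
        assert not np.array_equal(s1, s2)
        np.testing.assert_array_equal(
            np.round(s1 - network_signal(tiny_cros_raster, seed=1), 12),
            np.zeros(s1.size),
        )


class TestParameterSampling:
    def test_printed_diagonal(self):
        combos = sample_diagonal(30, 42, 0.5, 80)
        assert len(combos) == 25
        assert combos[0] == (30.0, 50.0)
        assert combos[-1] == (42.0, 38.0)
        assert all(ce + ci == 80.0 for ce, ci in combos)

    def test_coarse_diagonal(self):
        assert sample_diagonal(30, 42, 12, 80) == [(30.0, 50.0), (42.0, 38.0)]

    def test_phase_space_grid(self):
        grid = sample_phase_space(20, 100, 2)
        assert len(grid) == 1681
        assert (80.0, 80.0) in grid
        assert (20.0, 20.0) in grid and (100.0, 100.0) in grid

    def test_single_point_grid(self):
        assert sample_phase_space(20, 20, 2) == [(20.0, 20.0)]

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            sample_diagonal(step=0)
        with pytest.raises(ValueError):
            sample_phase_space(step=-1)
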