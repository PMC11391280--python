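"""K clustering surfaces, the derangement null and log-ratio behaviour."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_calls, stationary_gps
from vocalmap import spatial_clustering as sc
from vocalmap import synthetic_data as sd

LAGS = np.array([1.0, 10.0, 100.0, 1000.0])


class TestCallPairSurface:
    def test_point_mass_in_single_bin(self):
        # two individuals 3 m apart, all cross pairs within one lag bin
        calls = make_calls([("a0", "a", 10.0, 10.1, "cc"), ("b0", "b", 15.0, 15.1, "cc"),
                            ("a1", "a", 12.0, 12.1, "cc"), ("b1", "b", 17.0, 17.1, "cc")])
        gps = stationary_gps({"a": (0, 0), "b": (3.0, 0)}, t1=30.0)
        surf = sc.call_pair_surface(calls, gps, "cc", lag_edges=LAGS)
        # all 6 pairs have lags in [1, 10) except none; distances 0 or 3
        k_col = surf.K_obs[:, 0]
        assert np.nansum(k_col) == pytest.approx(1.0)
        # the 2-5 m bin (index 1) holds the 4 cross pairs; 0-2 m the 2 self pairs
        assert k_col[1] == pytest.approx(4 / 6)
        assert k_col[0] == pytest.approx(2 / 6)

    def test_row_sums_are_one_for_populated_lags(self, exchange_sim):
        surf = sc.call_pair_surface(exchange_sim.calls, exchange_sim.gps, "cc",
                                    lag_edges=sc.default_lag_edges(900.0, 8))
        sums = np.nansum(surf.K_obs, axis=0)
        assert np.allclose(sums[surf.n_pairs > 0], 1.0)

    def test_transect_matches_geometric_pair_distribution(self):
        # stationary callers every 5 m on a 100 m transect, calls uniform in
        # time: K at long lags ~ analytic pair-distance histogram
        rng = np.random.default_rng(5)
        positions = {f"i{k:02d}": (5.0 * k, 0.0) for k in range(21)}
        rows = []
        for ind in positions:
            for i, t in enumerate(np.sort(rng.uniform(0, 500, 40))):
                rows.append((f"{ind}_{i}", ind, t, t + 0.05, "cc"))
        calls = make_calls(rows)
        gps = stationary_gps(positions, t1=500.0)
        dist_edges = np.array([0.0, 10.0, 25.0, 50.0, 100.0])
        surf = sc.call_pair_surface(calls, gps, "cc", dist_edges=dist_edges,
                                    lag_edges=np.array([1.0, 500.0]))
        # analytic: caller pairs uniform over the 21 sites
        xs = np.array([5.0 * k for k in range(21)])
        d = np.abs(xs[:, None] - xs[None, :]).ravel()
        expect, _ = np.histogram(d, bins=dist_edges)
        expect = expect / expect.sum()
        got = surf.K_obs[:, 0]
        assert np.all(np.abs(got - expect) < 0.02)

    def test_merging_adjacent_distance_bins_is_exact(self, exchange_sim):
        fine = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 50.0])
        coarse = np.array([0.0, 5.0, 20.0, 50.0])
        lag = sc.default_lag_edges(900.0, 6)
        surf_f = sc.call_pair_surface(exchange_sim.calls, exchange_sim.gps, "cc",
                                      dist_edges=fine, lag_edges=lag)
        surf_c = sc.call_pair_surface(exchange_sim.calls, exchange_sim.gps, "cc",
                                      dist_edges=coarse, lag_edges=lag)
        merged = np.vstack([surf_f.K_obs[0] + surf_f.K_obs[1],
                            surf_f.K_obs[2] + surf_f.K_obs[3],
                            surf_f.K_obs[4]])
        mask = surf_f.n_pairs > 0
        assert np.allclose(merged[:, mask], surf_c.K_obs[:, mask], atol=1e-12)

    def test_no_gps_is_an_error(self):
        calls = make_calls([("a0", "a", 0, 0.1, "cc")])
        with pytest.raises(ValueError):
            sc.call_pair_surface(calls, calls.iloc[:0], "cc")


class TestShuffleNull:
    def test_two_individuals_swap_is_deterministic(self):
        calls = make_calls([("a0", "a", 10.0, 10.1, "cc"), ("b0", "b", 12.0, 12.1, "cc"),
                            ("a1", "a", 14.0, 14.1, "cc")])
        gps = stationary_gps({"a": (0, 0), "b": (3.0, 0)}, t1=30.0)
        surf = sc.shuffle_null(calls, gps, "cc", lag_edges=LAGS, n_perm=5, seed=0)
        # the only derangement of {a, b} swaps them; all perms identical
        for b in range(5):
            assert np.allclose(surf.K_null_all[b], surf.K_null_all[0], equal_nan=True)
        # stationary individuals: swapped distances equal the observed ones
        assert np.allclose(surf.K_obs, surf.K_null_mean, equal_nan=True)

    def test_derangement_has_no_fixed_points(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = sc._random_derangement(list("abcde"), rng)
            assert all(k != v for k, v in m.items())
            assert sorted(m.values()) == list("abcde")

    def test_position_independent_calls_give_flat_log_ratio(self):
        # broadcast mode with no speed gating: call times carry no spatial
        # information, so observed clustering matches the derangement null
        cfg = sd.SimConfig(n_individuals=6, session_s=900.0, seed=31,
                           broadcast=sd.BroadcastConfig(base_rate=0.08,
                                                        self_excitation_weight=0.3))
        sim = sd.simulate_session(cfg, "broadcast")
        surf = sc.shuffle_null(sim.calls, sim.gps, "sn",
                               lag_edges=sc.default_lag_edges(900.0, 6),
                               n_perm=60, seed=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            log_null = np.log(surf.K_null_all / surf.K_null_mean[None, :, :])
        se = np.nanstd(log_null, axis=0, ddof=1)
        cells = surf.n_pairs[None, :] * surf.K_obs  # pair counts per cell
        ok = np.isfinite(surf.log_ratio) & (cells >= 30) & (se > 0)
        assert ok.sum() >= 5
        assert np.all(np.abs(surf.log_ratio[ok]) < 3 * se[ok] + 1e-9)

    def test_exchange_clusters_within_response_radius(self, exchange_sim):
        surf = sc.shuffle_null(exchange_sim.calls, exchange_sim.gps, "cc",
                               lag_edges=np.array([1.0, 10.0, 60.0, 300.0]),
                               n_perm=40, seed=2)
        short = surf.log_ratio[1:3, 0]  # 2-5 m and 5-10 m, shortest lag
        far = surf.log_ratio[3, 0]      # 10-20 m: beyond the response radius
        assert np.nanmin(short) > 0
        assert far < 0

    def test_shuffle_null_invariant_on_preshuffled_data(self):
        # data whose audio-GPS link is already broken by one derangement is
        # statistically indistinguishable from its own shuffle null
        from scipy import stats as sps
        cfg = sd.SimConfig(n_individuals=6, session_s=900.0, seed=55,
                           broadcast=sd.BroadcastConfig(base_rate=0.08))
        sim = sd.simulate_session(cfg, "broadcast")
        rng = np.random.default_rng(0)
        mapping = sc._random_derangement(sorted(sim.gps["individual_id"].unique()), rng)
        pre = sim.calls.copy()
        pre["individual_id"] = pre["individual_id"].map(mapping)
        kw = dict(lag_edges=sc.default_lag_edges(900.0, 5), n_perm=40)
        surf = sc.shuffle_null(pre, sim.gps, "sn", seed=1, **kw)
        obs_cells = surf.K_obs[np.isfinite(surf.log_ratio)]
        null_cells = np.nanmean(surf.K_null_all, axis=0)[np.isfinite(surf.log_ratio)]
        p = sps.ks_2samp(obs_cells, null_cells).pvalue
        assert p > 0.01

    def test_shuffle_conserves_counts(self, exchange_sim):
        surf = sc.shuffle_null(exchange_sim.calls, exchange_sim.gps, "cc",
                               lag_edges=sc.default_lag_edges(900.0, 6),
                               n_perm=3, seed=3)
        # every permutation bins the same call multiset: with full GPS
        # coverage the total pair count per lag bin is conserved
        obs_tot = surf.n_pairs
        for b in range(3):
            null_tot = np.nansum(surf.K_null_all[b] * obs_tot[None, :], axis=0)
            # columns normalized: verify against raw recomputation instead
            assert np.allclose(np.nansum(surf.K_null_all[b], axis=0)[obs_tot > 0], 1.0)


class TestLogRatio:
    def test_equal_surfaces_give_zero(self):
        K = np.array([[0.5, 0.5], [0.5, 0.5]])
        surf = sc.ClusteringSurface(dist_edges=np.array([0, 1, 2.0]),
                                    lag_edges=np.array([0, 1, 2.0]),
                                    K_obs=K, n_pairs=np.array([4, 4]),
                                    K_null_mean=K.copy())
        assert np.allclose(sc.log_ratio_surface(surf), 0.0)

    def test_doubled_cell_gives_log2(self):
        K = np.array([[0.5, 0.5], [0.5, 0.5]])
        K2 = K.copy()
        K2[0, 0] = 1.0
        surf = sc.ClusteringSurface(dist_edges=np.array([0, 1, 2.0]),
                                    lag_edges=np.array([0, 1, 2.0]),
                                    K_obs=K2, n_pairs=np.array([4, 4]),
                                    K_null_mean=K)
        assert sc.log_ratio_surface(surf)[0, 0] == pytest.approx(np.log(2.0))

    def test_grid_mismatch_errors(self):
        surf = sc.ClusteringSurface(dist_edges=np.array([0, 1.0]),
                                    lag_edges=np.array([0, 1.0]),
                                    K_obs=np.ones((1, 1)), n_pairs=np.array([1]),
                                    K_null_mean=np.ones((2, 1)))
        with pytest.raises(ValueError):
            sc.log_ratio_surface(surf)
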