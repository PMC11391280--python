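"""Aggregate spatiotemporal clustering of calls: the K surface and its null.

For every unordered pair of same-category calls in a session, the pair is
binned by (caller–caller distance at the earlier call's onset, |Δt|).  The
clustering statistic K normalizes each (distance, lag) count by the total
number of pairs in the same lag bin, so each populated lag-bin column of K
sums to 1 and can be read as "the fraction of call pairs at this time
separation that were this far apart".

The null preserves both the group's spatial configuration and every
individual's calling sequence while breaking the link between them: per
session and permutation, a uniform random derangement re-assigns each
individual's call stream to another individual's trajectory, and K is
recomputed.  The natural-log ratio of observed K to the permutation mean
highlights scales at which calls cluster more (positive) or less (negative)
than the group's movement alone explains — persistent "vocal hotspots".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response_dynamics import iter_sessions
from .sequence_analysis import _positions_at

logger = logging.getLogger(__name__)

DEFAULT_DIST_EDGES = (0.0, 2.0, 5.0, 10.0, 20.0, 50.0)


def default_lag_edges(max_lag_s: float = 3600.0, n_bins: int = 12) -> np.ndarray:
    """Log-spaced lag-bin edges from 1 s to ``max_lag_s``."""
    return np.logspace(0.0, np.log10(max_lag_s), n_bins + 1)


@dataclass
class ClusteringSurface:
    dist_edges: np.ndarray
    lag_edges: np.ndarray
    K_obs: np.ndarray            # (n_dist, n_lag); columns sum to 1 where populated
    n_pairs: np.ndarray          # per lag bin
    K_null_mean: np.ndarray | None = None
    K_null_all: np.ndarray | None = None   # (n_perm, n_dist, n_lag)
    log_ratio: np.ndarray | None = None
    n_perm: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in range(len(self.dist_edges) - 1):
            for l in range(len(self.lag_edges) - 1):
                rows.append({
                    "dist_lo": self.dist_edges[d], "dist_hi": self.dist_edges[d + 1],
                    "lag_lo": self.lag_edges[l], "lag_hi": self.lag_edges[l + 1],
                    "K_obs": self.K_obs[d, l],
                    "K_null_mean": (self.K_null_mean[d, l]
                                    if self.K_null_mean is not None else np.nan),
                    "log_ratio": (self.log_ratio[d, l]
                                  if self.log_ratio is not None else np.nan),
                    "n_pairs": int(self.n_pairs[l]),
                })
        return pd.DataFrame(rows)


def _pair_histogram(calls: pd.DataFrame, trajs: pd.DataFrame, category: str,
                    dist_edges: np.ndarray, lag_edges: np.ndarray,
                    stream_of: dict[str, str] | None = None) -> np.ndarray:
    """Raw (distance, lag) pair counts for one session.

    ``stream_of`` maps a trajectory owner to the individual whose call stream
    rides on it (identity if None) — the hook the derangement null uses.
    Calls without a usable fix at the earlier call's time are skipped.
    """
    counts = np.zeros((len(dist_edges) - 1, len(lag_edges) - 1))
    cat = calls[calls["category"] == category].sort_values(
        ["t_start", "individual_id", "event_id"], kind="stable")
    if len(cat) < 2:
        return counts
    pos = _positions_at(trajs)
    # call stream owner -> trajectory owner
    traj_of = {v: k for k, v in stream_of.items()} if stream_of else {}

    t = cat["t_start"].to_numpy()
    who = cat["individual_id"].to_numpy()
    carriers = sorted({traj_of.get(w, w) for w in who})
    c_index = {c: k for k, c in enumerate(carriers)}
    carrier_idx = np.array([c_index[traj_of.get(w, w)] for w in who])

    # POS[c, i] = position of carrier c at call time t[i] (NaN if no fix ±1 s)
    n = len(cat)
    POSx = np.full((len(carriers), n), np.nan)
    POSy = np.full((len(carriers), n), np.nan)
    for c, k in c_index.items():
        if c not in pos:
            continue
        ts, xs, ys = pos[c]
        j = np.clip(np.searchsorted(ts, t), 0, len(ts) - 1)
        j_prev = np.clip(j - 1, 0, len(ts) - 1)
        pick = np.where(np.abs(ts[j_prev] - t) <= np.abs(ts[j] - t), j_prev, j)
        ok = np.abs(ts[pick] - t) <= 1.0
        POSx[k, ok] = xs[pick[ok]]
        POSy[k, ok] = ys[pick[ok]]

    max_lag = lag_edges[-1]
    n_d, n_l = counts.shape
    for i in range(n - 1):
        ci = carrier_idx[i]
        if not np.isfinite(POSx[ci, i]):
            continue
        j_hi = np.searchsorted(t, t[i] + max_lag, side="right")
        js = np.arange(i + 1, j_hi)
        if len(js) == 0:
            continue
        cj = carrier_idx[js]
        # distance measured at the earlier call's onset
        dx = POSx[cj, i] - POSx[ci, i]
        dy = POSy[cj, i] - POSy[ci, i]
        ok = np.isfinite(dx)
        if not np.any(ok):
            continue
        d = np.hypot(dx[ok], dy[ok])
        lag = t[js[ok]] - t[i]
        li = np.searchsorted(lag_edges, lag, side="right") - 1
        di = np.searchsorted(dist_edges, d, side="right") - 1
        keep = (li >= 0) & (li < n_l) & (di >= 0) & (di < n_d)
        np.add.at(counts, (di[keep], li[keep]), 1)
    return counts


def _normalize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_pairs = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(n_pairs[None, :] > 0, counts / n_pairs[None, :], np.nan)
    return K, n_pairs


def call_pair_surface(
    calls: pd.DataFrame,
    trajs: pd.DataFrame,
    category: str,
    *,
    dist_edges=DEFAULT_DIST_EDGES,
    lag_edges=None,
) -> ClusteringSurface:
    """Observed K over (distance, lag) bins; all call pairs, per session.

    All unordered same-session pairs of the category (not only consecutive
    calls) are binned; counts pool across sessions before normalization.
    """
    dist_edges = np.asarray(dist_edges, dtype=float)
    lag_edges = np.asarray(lag_edges, dtype=float) if lag_edges is not None else default_lag_edges()
    if trajs is None or len(trajs) == 0:
        raise ValueError("GPS trajectories are required for the clustering surface")
    counts = np.zeros((len(dist_edges) - 1, len(lag_edges) - 1))
    for _, s_calls, s_trajs in iter_sessions(calls, trajs):
        counts += _pair_histogram(s_calls, s_trajs, category, dist_edges, lag_edges)
    K, n_pairs = _normalize(counts)
    return ClusteringSurface(dist_edges=dist_edges, lag_edges=lag_edges,
                             K_obs=K, n_pairs=n_pairs)


def _random_derangement(items: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Uniform random derangement by rejection sampling."""
    n = len(items)
    if n < 2:
        raise ValueError("a derangement needs at least 2 individuals")
    idx = np.arange(n)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == idx):
            return {items[i]: items[perm[i]] for i in range(n)}


def shuffle_null(
    calls: pd.DataFrame,
    trajs: pd.DataFrame,
    category: str,
    *,
    dist_edges=DEFAULT_DIST_EDGES,
    lag_edges=None,
    n_perm: int = 100,
    seed: int = 0,
) -> ClusteringSurface:
    """Observed K plus the audio–GPS derangement null and log-ratio surface.

    Per permutation and session, each GPS-bearing individual's call stream is
    re-assigned to another individual's trajectory via a uniform random
    derangement (no fixed points); K is recomputed and averaged over
    permutations.  Sessions with fewer than two GPS-bearing individuals are
    skipped with a warning.
    """
    dist_edges = np.asarray(dist_edges, dtype=float)
    lag_edges = np.asarray(lag_edges, dtype=float) if lag_edges is not None else default_lag_edges()
    rng = np.random.default_rng(seed)

    obs_counts = np.zeros((len(dist_edges) - 1, len(lag_edges) - 1))
    null_counts = np.zeros((n_perm, len(dist_edges) - 1, len(lag_edges) - 1))
    for key, s_calls, s_trajs in iter_sessions(calls, trajs):
        gps_inds = sorted(s_trajs["individual_id"].unique())
        obs_counts += _pair_histogram(s_calls, s_trajs, category, dist_edges, lag_edges)
        if len(gps_inds) < 2:
            logger.warning("session %s: <2 GPS individuals, skipped in shuffle null", key)
            continue
        for b in range(n_perm):
            stream_of = _random_derangement(gps_inds, rng)
            null_counts[b] += _pair_histogram(
                s_calls, s_trajs, category, dist_edges, lag_edges, stream_of=stream_of)

    K_obs, n_pairs = _normalize(obs_counts)
    K_null = np.stack([_normalize(null_counts[b])[0] for b in range(n_perm)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        K_null_mean = np.nanmean(K_null, axis=0)
    surface = ClusteringSurface(
        dist_edges=dist_edges, lag_edges=lag_edges, K_obs=K_obs, n_pairs=n_pairs,
        K_null_mean=K_null_mean, K_null_all=K_null, n_perm=n_perm)
    surface.log_ratio = log_ratio_surface(surface)
    return surface


def log_ratio_surface(surface: ClusteringSurface,
                      K_obs: np.ndarray | None = None,
                      K_null_mean: np.ndarray | None = None) -> np.ndarray:
    """Natural-log ratio of observed to null-mean K, NaN where undefined."""
    K_obs = surface.K_obs if K_obs is None else K_obs
    K_null_mean = surface.K_null_mean if K_null_mean is None else K_null_mean
    if K_obs.shape != K_null_mean.shape:
        raise ValueError("K_obs and K_null_mean grids do not match")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((K_null_mean > 0) & np.isfinite(K_obs) & (K_obs > 0),
                         np.log(K_obs / K_null_mean), np.nan)
    return ratio
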