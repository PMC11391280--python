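"""Individual call-rate series and their dependence on movement and neighbours.

Per individual, the raw call rate is the count of call onsets in a trailing
10 s window evaluated on a 1 Hz grid; z-scoring over the context-eligible
windows (mean 0, SD 1 per individual) makes individuals with different
baseline rates comparable.  The covariates are the individual's net-
displacement speed over the same window (m/min) and the number of tracked
conspecifics within 5 m.  Binned profiles — 10 speed-quantile bins, or
0/1/2/3/4+ neighbours — average z-rates first within and then across
individuals (each individual one vote), exposing e.g. a speed-gated calling
regime as a step in the top speed bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ContextMask

NEIGHBOUR_BIN_LABELS = ("0", "1", "2", "3", "4+")


@dataclass
class RateSeries:
    individual_id: str
    t_grid: np.ndarray
    raw_rate: np.ndarray              # calls per window
    z_rate: np.ndarray | None = None  # NaN where ineligible
    degenerate: bool = False          # sigma == 0 over eligible windows


@dataclass
class BinnedRateProfile:
    covariate: str                    # 'speed' | 'n_neighbours'
    bin_labels: list[str]
    bin_edges: np.ndarray | None      # speed only
    per_individual: pd.DataFrame      # individual_id, bin, mean_z, n_obs
    grand_mean: pd.Series             # unweighted mean of individual means per bin
    pooled_mean: pd.Series            # pooled-observation mean per bin (diagnostic)
    n_obs: pd.Series                  # pooled observations per bin


def rolling_rate(calls: pd.DataFrame, individual: str, t_grid: np.ndarray,
                 *, window_s: float = 10.0, category: str | None = None) -> RateSeries:
    """Trailing-window call count per grid second: onsets in (t − window_s, t]."""
    sub = calls[calls["individual_id"] == individual]
    if category is not None:
        sub = sub[sub["category"] == category]
    onsets = np.sort(sub["t_start"].to_numpy())
    lo = np.searchsorted(onsets, t_grid - window_s, side="right")
    hi = np.searchsorted(onsets, t_grid, side="right")
    return RateSeries(individual_id=individual, t_grid=np.asarray(t_grid, dtype=float),
                      raw_rate=(hi - lo).astype(float))


def zscore(series: RateSeries, eligible: np.ndarray) -> RateSeries:
    """z-normalize over eligible windows; ineligible grid points become NaN.

    Series whose eligible windows have zero variance are flagged degenerate
    (z all-NaN) and should be excluded downstream.
    """
    eligible = np.asarray(eligible, dtype=bool)
    if eligible.shape != series.raw_rate.shape:
        raise ValueError("eligibility mask does not match the rate grid")
    z = np.full_like(series.raw_rate, np.nan, dtype=float)
    vals = series.raw_rate[eligible]
    if len(vals) < 2:
        return RateSeries(series.individual_id, series.t_grid, series.raw_rate,
                          z_rate=z, degenerate=True)
    mu, sigma = float(vals.mean()), float(vals.std(ddof=0))
    if sigma == 0.0:
        return RateSeries(series.individual_id, series.t_grid, series.raw_rate,
                          z_rate=z, degenerate=True)
    z[eligible] = (vals - mu) / sigma
    return RateSeries(series.individual_id, series.t_grid, series.raw_rate,
                      z_rate=z, degenerate=False)


def speed_series(traj: pd.DataFrame, t_grid: np.ndarray, *, window_s: float = 10.0) -> np.ndarray:
    """Net-displacement speed in m/min per grid point; NaN if either endpoint
    fix (at t − window_s or t, nearest valid fix within ±1 s) is missing."""
    use = traj[traj["valid"]] if "valid" in traj.columns else traj
    use = use.sort_values("t")
    ts = use["t"].to_numpy()
    xs = use["x"].to_numpy()
    ys = use["y"].to_numpy()

    def _at(times: np.ndarray):
        if len(ts) == 0:
            return np.full(len(times), np.nan), np.full(len(times), np.nan)
        j = np.clip(np.searchsorted(ts, times), 0, len(ts) - 1)
        jp = np.clip(j - 1, 0, len(ts) - 1)
        pick = np.where(np.abs(ts[jp] - times) <= np.abs(ts[j] - times), jp, j)
        ok = np.abs(ts[pick] - times) <= 1.0
        x = np.where(ok, xs[pick], np.nan)
        y = np.where(ok, ys[pick], np.nan)
        return x, y

    t_grid = np.asarray(t_grid, dtype=float)
    x1, y1 = _at(t_grid)
    x0, y0 = _at(t_grid - window_s)
    return np.hypot(x1 - x0, y1 - y0) / window_s * 60.0


def neighbour_count(trajs: pd.DataFrame, individual: str, t_grid: np.ndarray,
                    *, radius_m: float = 5.0) -> np.ndarray:
    """Tracked conspecifics with a valid fix within ``radius_m`` per grid second.

    NaN where the focal individual itself has no valid fix (distance to it is
    undefined); untracked animals are invisible, as with audio-only collars.
    """
    use = trajs[trajs["valid"]] if "valid" in trajs.columns else trajs
    t_grid = np.asarray(t_grid, dtype=float)

    def _grid_positions(sub: pd.DataFrame):
        sub = sub.sort_values("t")
        ts, xs, ys = sub["t"].to_numpy(), sub["x"].to_numpy(), sub["y"].to_numpy()
        if len(ts) == 0:
            return np.full(len(t_grid), np.nan), np.full(len(t_grid), np.nan)
        j = np.clip(np.searchsorted(ts, t_grid), 0, len(ts) - 1)
        jp = np.clip(j - 1, 0, len(ts) - 1)
        pick = np.where(np.abs(ts[jp] - t_grid) <= np.abs(ts[j] - t_grid), jp, j)
        ok = np.abs(ts[pick] - t_grid) <= 0.5
        return np.where(ok, xs[pick], np.nan), np.where(ok, ys[pick], np.nan)

    fx, fy = _grid_positions(use[use["individual_id"] == individual])
    count = np.zeros(len(t_grid))
    for other, sub in use.groupby("individual_id", observed=True):
        if other == individual:
            continue
        ox, oy = _grid_positions(sub)
        d = np.hypot(ox - fx, oy - fy)
        count += (d <= radius_m) & np.isfinite(d)
    count[~np.isfinite(fx)] = np.nan
    return count


def binned_profile(
    z_by_individual: dict[str, RateSeries],
    covariate_by_individual: dict[str, np.ndarray],
    mask: ContextMask | np.ndarray,
    *,
    covariate: str = "speed",
    n_speed_bins: int = 10,
    min_hours: float = 2.0,
) -> BinnedRateProfile:
    """Within- then across-individual bin means of z-rates versus a covariate.

    Speed bins are quantile bins of the pooled eligible speed distribution
    across individuals (near-equal occupancy); neighbour bins are
    0/1/2/3/4+.  Individuals with fewer than ``min_hours`` of eligible,
    covariate-complete seconds are dropped; an error is raised if none
    survive.  The grand mean weights every surviving individual equally; the
    pooled mean (every observation equally) is returned as a diagnostic.
    """
    eligible = mask.eligible if isinstance(mask, ContextMask) else np.asarray(mask, dtype=bool)

    frames = []
    for ind, series in z_by_individual.items():
        if series.degenerate:
            continue
        cov = np.asarray(covariate_by_individual[ind], dtype=float)
        ok = eligible & np.isfinite(series.z_rate) & np.isfinite(cov)
        if ok.sum() < min_hours * 3600.0:
            continue
        frames.append(pd.DataFrame({
            "individual_id": ind, "z": series.z_rate[ok], "cov": cov[ok]}))
    if not frames:
        raise ValueError("no individual has enough eligible data for the binned profile")
    data = pd.concat(frames, ignore_index=True)

    if covariate == "speed":
        edges = np.quantile(data["cov"], np.linspace(0, 1, n_speed_bins + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        labels = [f"q{i+1}" for i in range(n_speed_bins)]
        data["bin"] = pd.cut(data["cov"], bins=edges, labels=labels, include_lowest=True)
        bin_edges = np.quantile(data["cov"], np.linspace(0, 1, n_speed_bins + 1))
    elif covariate == "n_neighbours":
        labels = list(NEIGHBOUR_BIN_LABELS)
        data["bin"] = pd.cut(data["cov"], bins=[-0.5, 0.5, 1.5, 2.5, 3.5, np.inf],
                             labels=labels)
        bin_edges = None
    else:
        raise ValueError(f"unknown covariate {covariate!r}")

    per_ind = (data.groupby(["individual_id", "bin"], observed=False)["z"]
               .agg(["mean", "size"]).reset_index()
               .rename(columns={"mean": "mean_z", "size": "n_obs"}))
    grand = per_ind.groupby("bin", observed=False)["mean_z"].mean()
    pooled = data.groupby("bin", observed=False)["z"].mean()
    n_obs = data.groupby("bin", observed=False)["z"].size()
    grand = grand.reindex(labels)
    return BinnedRateProfile(covariate=covariate, bin_labels=labels, bin_edges=bin_edges,
                             per_individual=per_ind, grand_mean=grand,
                             pooled_mean=pooled.reindex(labels),
                             n_obs=n_obs.reindex(labels).fillna(0).astype(int))
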