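"""Kernel-smoothed peri-call responder rate curves.

For every focal call and every potential responder (any other individual),
the responder's call onsets in a window around the focal call are
accumulated and smoothed with a Gaussian kernel, yielding the responder
calling rate (calls/s) as a function of time relative to the focal call
(t = 0 at focal onset).  Curves are stratified either by caller–responder
distance at the focal onset (0–2, 2–5, 5–10, 10–50 m by default) or by the
(caller age, responder age) pair; antiphonal exchange shows symmetric
off-zero peaks (a call is answered ~0.4 s later, and equally often *was* an
answer to a call ~0.4 s earlier), whereas broadcast calling gives flat or
centre-peaked curves.

All accumulation is per session (group-day): times are seconds since the
session's UTC midnight, so pooling across days is done on the accumulators,
never on the raw timelines.  Uncertainty comes from a day-level bootstrap:
session-days are resampled with replacement within each group, keeping the
observed per-group day count, and all curves are recomputed per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_analysis import _position_near, _positions_at

DEFAULT_DISTANCE_BINS = ((0.0, 2.0), (2.0, 5.0), (5.0, 10.0), (10.0, 50.0))


@dataclass
class ResponseCurve:
    stratum: str                 # e.g. '0-2m' or 'adult->juvenile'
    t_grid: np.ndarray           # seconds relative to focal onset
    rate: np.ndarray             # mean responder calls/s per grid point
    n_pairs: int                 # (focal, responder) pairs contributing
    n_focal: int                 # distinct focal calls contributing

    def peak_lag(self, search: tuple[float, float] | None = None) -> float:
        """Lag of the maximum rate, optionally restricted to a lag window."""
        mask = np.ones_like(self.t_grid, dtype=bool)
        if search is not None:
            mask = (self.t_grid >= search[0]) & (self.t_grid <= search[1])
        idx = np.flatnonzero(mask)
        return float(self.t_grid[idx[np.argmax(self.rate[idx])]])


@dataclass
class CoverageReport:
    n_focal_calls: int = 0
    n_pairs_used: int = 0
    n_pairs_skipped_gps: int = 0


@dataclass
class BootstrapSet:
    observed: dict[str, ResponseCurve]
    replicates: list[dict[str, ResponseCurve]] = field(default_factory=list)
    n_boot: int = 0
    seed: int = 0


def _dist_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}m"


def _kernel_accumulate(rel_times: np.ndarray, t_grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Sum of unit-mass Gaussian kernels centred on each relative event time."""
    if len(rel_times) == 0:
        return np.zeros_like(t_grid)
    z = (t_grid[None, :] - rel_times[:, None]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=0) / (bandwidth * np.sqrt(2.0 * np.pi))


def iter_sessions(calls: pd.DataFrame, trajs: pd.DataFrame | None):
    """Yield (key, session_calls, session_trajs) per (group_id, session_date).

    If the trajectory frame carries no ``session_date`` column it is assumed
    to belong to the single session present in the calls.
    """
    for key, sub in calls.groupby(["group_id", "session_date"], observed=True, sort=True):
        if trajs is None:
            yield key, sub, None
        elif "session_date" in trajs.columns:
            yield key, sub, trajs[trajs["session_date"] == key[1]]
        else:
            yield key, sub, trajs


class _CurveAccumulator:
    def __init__(self, strata: list[str], t_grid: np.ndarray):
        self.t_grid = t_grid
        self.acc = {s: np.zeros_like(t_grid) for s in strata}
        self.n_pairs = {s: 0 for s in strata}
        self.focal: dict[str, set] = {s: set() for s in strata}

    def add(self, stratum: str, contribution: np.ndarray, focal_id) -> None:
        self.acc[stratum] += contribution
        self.n_pairs[stratum] += 1
        self.focal[stratum].add(focal_id)

    def curves(self) -> list[ResponseCurve]:
        out = []
        for s, a in self.acc.items():
            n = self.n_pairs[s]
            out.append(ResponseCurve(
                stratum=s, t_grid=self.t_grid.copy(),
                rate=a / n if n else np.zeros_like(self.t_grid),
                n_pairs=n, n_focal=len(self.focal[s])))
        return out


def peri_call_rate(
    calls: pd.DataFrame,
    trajs: pd.DataFrame,
    category: str,
    *,
    distance_bins=DEFAULT_DISTANCE_BINS,
    t_range: tuple[float, float] = (-5.0, 5.0),
    grid_step: float = 0.05,
    bandwidth: float = 0.1,
) -> tuple[list[ResponseCurve], CoverageReport]:
    """Distance-stratified responder rate curves around focal calls.

    Works on the note-level timeline of one category.  For each (focal call,
    responder) pair with GPS for both at the focal onset (nearest valid fix
    within ±1 s, else the pair is skipped and counted in the coverage
    report), responder onsets in ``t_range`` are kernel-accumulated; each
    stratum's curve is the mean over its contributing pairs, i.e. the
    average responder calling rate in calls/s.
    """
    t_grid = np.arange(t_range[0], t_range[1] + grid_step / 2, grid_step)
    strata = [_dist_label(*b) for b in distance_bins]
    accum = _CurveAccumulator(strata, t_grid)
    report = CoverageReport()

    for _, s_calls, s_trajs in iter_sessions(calls, trajs):
        cat_calls = s_calls[s_calls["category"] == category]
        report.n_focal_calls += len(cat_calls)
        pos = _positions_at(s_trajs)
        onsets_by_ind = {
            ind: np.sort(grp["t_start"].to_numpy())
            for ind, grp in cat_calls.groupby("individual_id", observed=True)
        }
        individuals = sorted(set(s_calls["individual_id"]) | set(pos))

        for row in cat_calls.itertuples(index=False):
            t0 = float(row.t_start)
            caller_pos = _position_near(pos, row.individual_id, t0)
            if caller_pos is None:
                report.n_pairs_skipped_gps += len(individuals) - 1
                continue
            for other in individuals:
                if other == row.individual_id:
                    continue
                other_pos = _position_near(pos, other, t0)
                if other_pos is None:
                    report.n_pairs_skipped_gps += 1
                    continue
                d = float(np.hypot(other_pos[0] - caller_pos[0],
                                   other_pos[1] - caller_pos[1]))
                label = None
                for (lo, hi), lab in zip(distance_bins, strata):
                    if lo <= d < hi:
                        label = lab
                        break
                if label is None:
                    continue
                onsets = onsets_by_ind.get(other, np.empty(0))
                lo_i = np.searchsorted(onsets, t0 + t_range[0])
                hi_i = np.searchsorted(onsets, t0 + t_range[1])
                accum.add(label, _kernel_accumulate(onsets[lo_i:hi_i] - t0, t_grid, bandwidth),
                          row.event_id)
                report.n_pairs_used += 1

    return accum.curves(), report


def age_class_curves(
    calls: pd.DataFrame,
    category: str,
    *,
    t_range: tuple[float, float] = (-5.0, 5.0),
    grid_step: float = 0.05,
    bandwidth: float = 0.1,
) -> list[ResponseCurve]:
    """(caller age, responder age)-stratified curves, no distance subsetting.

    Requires an ``age_class`` for every individual (error names the missing
    ones); needs no GPS, so juveniles participate fully.
    """
    ages = (calls[["individual_id", "age_class"]].drop_duplicates()
            .set_index("individual_id")["age_class"].to_dict())
    missing = sorted(i for i, a in ages.items() if a not in ("adult", "juvenile"))
    if missing:
        raise ValueError(f"missing/unknown age_class for individuals: {', '.join(missing)}")

    t_grid = np.arange(t_range[0], t_range[1] + grid_step / 2, grid_step)
    strata = [f"{a}->{b}" for a in ("adult", "juvenile") for b in ("adult", "juvenile")]
    accum = _CurveAccumulator(strata, t_grid)

    for _, s_calls, _ in iter_sessions(calls, None):
        cat_calls = s_calls[s_calls["category"] == category]
        onsets_by_ind = {
            ind: np.sort(grp["t_start"].to_numpy())
            for ind, grp in cat_calls.groupby("individual_id", observed=True)
        }
        individuals = sorted(set(s_calls["individual_id"]))
        for row in cat_calls.itertuples(index=False):
            t0 = float(row.t_start)
            for other in individuals:
                if other == row.individual_id:
                    continue
                label = f"{ages[row.individual_id]}->{ages[other]}"
                onsets = onsets_by_ind.get(other, np.empty(0))
                lo_i = np.searchsorted(onsets, t0 + t_range[0])
                hi_i = np.searchsorted(onsets, t0 + t_range[1])
                accum.add(label, _kernel_accumulate(onsets[lo_i:hi_i] - t0, t_grid, bandwidth),
                          row.event_id)

    return accum.curves()


def bootstrap_days(
    calls: pd.DataFrame,
    trajs: pd.DataFrame,
    category: str,
    *,
    n_boot: int = 100,
    seed: int = 0,
    **curve_kwargs,
) -> BootstrapSet:
    """Day-level bootstrap of the distance-stratified curves.

    Per replicate, each group's session-days are resampled with replacement
    (keeping the observed per-group day count); calls and trajectories of a
    drawn day are relabelled as a fresh pseudo-day, so repeated draws
    contribute repeatedly.  Deterministic for a given seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    obs_curves, _ = peri_call_rate(calls, trajs, category, **curve_kwargs)
    observed = {c.stratum: c for c in obs_curves}

    groups = calls.groupby("group_id", observed=True)["session_date"].unique().to_dict()
    traj_has_day = "session_date" in trajs.columns

    replicates = []
    for _ in range(n_boot):
        call_parts, traj_parts = [], []
        for gid, days in groups.items():
            draw = rng.choice(np.sort(days), size=len(days), replace=True)
            for k, day in enumerate(draw):
                pseudo = f"{day}#r{k}"
                sub = calls[(calls["group_id"] == gid) & (calls["session_date"] == day)].copy()
                sub["session_date"] = pseudo
                call_parts.append(sub)
                if traj_has_day:
                    tsub = trajs[trajs["session_date"] == day].copy()
                    tsub["session_date"] = pseudo
                    traj_parts.append(tsub)
        rep_calls = pd.concat(call_parts, ignore_index=True)
        rep_trajs = pd.concat(traj_parts, ignore_index=True) if traj_has_day else trajs
        rep_curves, _ = peri_call_rate(rep_calls, rep_trajs, category, **curve_kwargs)
        replicates.append({c.stratum: c for c in rep_curves})
    return BootstrapSet(observed=observed, replicates=replicates, n_boot=n_boot, seed=seed)


def curves_to_frame(curve_sets: dict[int, dict[str, ResponseCurve]]) -> pd.DataFrame:
    """Long-format export: replicate_id (0 = observed), stratum, t, rate."""
    rows = []
    for rep_id, curves in curve_sets.items():
        for stratum, c in curves.items():
            rows.append(pd.DataFrame({
                "replicate_id": rep_id, "stratum": stratum, "t": c.t_grid, "rate": c.rate}))
    return pd.concat(rows, ignore_index=True)
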