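"""GPS cleaning, note merging, category collapsing and context eligibility.

Mirrors the standard pre-analysis steps for collar-based group tracking:

* :func:`clean_gps` — satellite-count filter, a ±60 s buffer around signal-loss
  gaps in the nominal 1 Hz stream, and an implausible-step (>10 m between
  consecutive fixes) filter.  Fixes are *flagged* invalid rather than dropped,
  which keeps the recorded timestamp stream intact and makes the operation
  idempotent.
* :func:`merge_notes` — collapses runs of same-individual, same-category notes
  separated by <0.1 s of silence into single multi-note calls.
* :func:`collapse_categories` — maps free-text labels (including "A/B" hybrid
  forms) onto the closed 8-level category vocabulary using dataset abundances.
* :func:`build_context_mask` — the per-second eligibility mask used by the
  call-rate analyses: enough individuals tracked, the group foraging, and no
  recent alarm call.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events_io import CATEGORIES, CallEvent, Session

logger = logging.getLogger(__name__)

# reason bit flags for ContextMask
TOO_FEW_TRACKED = 1
NOT_FORAGING = 2
RECENT_ALARM = 4


@dataclass
class CleaningReport:
    """Bookkeeping for :func:`clean_gps`: how many fixes each rule invalidated."""

    n_input_fixes: int = 0
    n_removed_satellites: int = 0
    n_removed_gap_buffer: int = 0
    n_removed_speed: int = 0

    @property
    def n_output_fixes(self) -> int:
        return (
            self.n_input_fixes
            - self.n_removed_satellites
            - self.n_removed_gap_buffer
            - self.n_removed_speed
        )

    def __add__(self, other: "CleaningReport") -> "CleaningReport":
        return CleaningReport(
            self.n_input_fixes + other.n_input_fixes,
            self.n_removed_satellites + other.n_removed_satellites,
            self.n_removed_gap_buffer + other.n_removed_gap_buffer,
            self.n_removed_speed + other.n_removed_speed,
        )

    def to_dict(self) -> dict:
        return {
            "n_input_fixes": self.n_input_fixes,
            "n_removed_satellites": self.n_removed_satellites,
            "n_removed_gap_buffer": self.n_removed_gap_buffer,
            "n_removed_speed": self.n_removed_speed,
            "n_output_fixes": self.n_output_fixes,
        }


@dataclass
class ContextMask:
    """Per-second eligibility grid with per-point reason bit flags."""

    t_grid: np.ndarray
    reasons: np.ndarray  # uint8 bit flags; 0 == eligible
    flags: dict = field(default_factory=dict)

    @property
    def eligible(self) -> np.ndarray:
        return self.reasons == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t_grid,
                "eligible": self.eligible,
                "too_few_tracked": (self.reasons & TOO_FEW_TRACKED) > 0,
                "not_foraging": (self.reasons & NOT_FORAGING) > 0,
                "recent_alarm": (self.reasons & RECENT_ALARM) > 0,
            }
        )


def clean_gps(
    fixes: pd.DataFrame,
    *,
    min_satellites: int = 5,
    gap_buffer_s: float = 60.0,
    max_step_m: float = 10.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Quality-filter a GPS frame, returning it with ``valid`` updated.

    Three rules are applied per individual, in order, each operating on the
    fixes still valid after the previous one:

    1. fixes with fewer than ``min_satellites`` satellites are invalidated;
    2. fixes within ``gap_buffer_s`` seconds before or after a signal-loss
       gap (an inter-timestamp gap >1 s in the *recorded* stream, valid or
       not) are invalidated;
    3. a greedy forward scan invalidates the later fix of any consecutive
       valid pair more than ``max_step_m`` apart, then re-evaluates against
       the last kept fix.

    Rows are never dropped, so reapplying the function is a no-op (an
    all-zero report).  Input must be sorted by (individual_id, t).
    """
    t = fixes["t"].to_numpy()
    ind = fixes["individual_id"].to_numpy()
    order = np.lexsort((t, ind))
    if not np.array_equal(order, np.arange(len(fixes))):
        raise ValueError("fixes must be sorted by (individual_id, t)")

    out = fixes.copy()
    report = CleaningReport(n_input_fixes=int(out["valid"].sum()))
    valid = out["valid"].to_numpy().copy()
    x = out["x"].to_numpy()
    y = out["y"].to_numpy()
    sats = out["n_satellites"].to_numpy()

    for _, idx in pd.Series(range(len(out))).groupby(ind, sort=False):
        ii = idx.to_numpy()
        ti = t[ii]

        # rule 1: satellite count
        bad_sat = valid[ii] & (sats[ii] < min_satellites)
        report.n_removed_satellites += int(bad_sat.sum())
        valid[ii[bad_sat]] = False

        # rule 2: buffer around gaps in the recorded timestamp stream
        gaps = np.flatnonzero(np.diff(ti) > 1.0)
        if len(gaps):
            near_gap = np.zeros(len(ii), dtype=bool)
            for g in gaps:
                lo, hi = ti[g], ti[g + 1]
                near_gap |= (ti > lo - gap_buffer_s) & (ti <= lo)
                near_gap |= (ti >= hi) & (ti < hi + gap_buffer_s)
            bad_gap = valid[ii] & near_gap
            report.n_removed_gap_buffer += int(bad_gap.sum())
            valid[ii[bad_gap]] = False

        # rule 3: implausible step, greedy forward scan over surviving fixes
        alive = ii[valid[ii]]
        if len(alive) >= 2:
            last = alive[0]
            for j in alive[1:]:
                step = float(np.hypot(x[j] - x[last], y[j] - y[last]))
                if step > max_step_m:
                    valid[j] = False
                    report.n_removed_speed += 1
                else:
                    last = j

    out["valid"] = valid
    return out, report


def merge_notes(events: list[CallEvent], *, max_gap_s: float = 0.1) -> list[CallEvent]:
    """Collapse runs of quick-succession same-category notes into single calls.

    Within one individual's time-sorted stream, consecutive events of the same
    category whose inter-note silence (next onset minus previous offset) is
    strictly below ``max_gap_s`` merge into one call spanning first onset to
    last offset; ``n_notes`` sums over the run, so the total note count is
    preserved.
    """
    by_ind: dict[str, list[CallEvent]] = {}
    for e in events:
        by_ind.setdefault(e.individual_id, []).append(e)

    merged: list[CallEvent] = []
    for ind_events in by_ind.values():
        ind_events.sort(key=lambda e: (e.t_start, e.event_id))
        run: list[CallEvent] = []
        for e in ind_events:
            if run and e.category == run[-1].category and (e.t_start - run[-1].t_end) < max_gap_s:
                run.append(e)
            else:
                if run:
                    merged.append(_collapse_run(run))
                run = [e]
        if run:
            merged.append(_collapse_run(run))
    merged.sort(key=lambda e: (e.t_start, e.individual_id, e.event_id))
    return merged


def _collapse_run(run: list[CallEvent]) -> CallEvent:
    if len(run) == 1:
        return run[0]
    head = run[0]
    return CallEvent(
        event_id=head.event_id,
        individual_id=head.individual_id,
        group_id=head.group_id,
        session_date=head.session_date,
        t_start=head.t_start,
        t_end=max(e.t_end for e in run),
        category=head.category,
        focal=head.focal,
        age_class=head.age_class,
        n_notes=sum(e.n_notes for e in run),
    )


_LABEL_TOKEN = re.compile(r"[a-z]+")


def collapse_categories(raw_label: str, category_abundance: dict[str, int]) -> str:
    """Map a free-text call label onto the closed category vocabulary.

    Canonical codes map to themselves.  Hybrid labels mentioning two
    categories ("cc/sn", "sn hybrid cc") resolve to the more abundant one in
    ``category_abundance`` (ties break alphabetically, logged).  Labels
    mentioning no known category return ``"ukn"``.
    """
    if not category_abundance:
        raise ValueError("empty category abundance table")
    label = raw_label.strip().lower()
    if label in CATEGORIES:
        return label
    mentioned = [tok for tok in _LABEL_TOKEN.findall(label) if tok in CATEGORIES]
    mentioned = list(dict.fromkeys(mentioned))  # dedupe, keep order
    if not mentioned:
        return "ukn"
    if len(mentioned) == 1:
        return mentioned[0]
    best = sorted(mentioned, key=lambda c: (-category_abundance.get(c, 0), c))
    if category_abundance.get(best[0], 0) == category_abundance.get(best[1], 0):
        logger.info("label %r: abundance tie between %s; choosing %s alphabetically",
                    raw_label, best[:2], best[0])
    return best[0]


def build_context_mask(
    calls: list[CallEvent],
    fixes: pd.DataFrame,
    session: Session,
    *,
    min_tracked: int = 5,
    foraging_frac: float = 0.5,
    lookback_s: float = 60.0,
) -> ContextMask:
    """Per-second eligibility mask for context-controlled call-rate analyses.

    A grid second ``t`` is eligible iff (a) at least ``min_tracked``
    individuals have a valid fix within ±1 s of ``t``; (b) at least
    ``foraging_frac`` of those tracked individuals emitted >=1 close call in
    the window ``(t - lookback_s, t]``; and (c) no group member emitted an
    alarm call in that window.  Each failing condition sets a reason bit.
    """
    t0, t1 = session.t_window
    t_grid = np.arange(np.floor(t0), np.floor(t1) + 1.0)
    n = len(t_grid)
    if n == 0:
        return ContextMask(t_grid=t_grid, reasons=np.zeros(0, dtype=np.uint8))
    reasons = np.zeros(n, dtype=np.uint8)

    valid = fixes[fixes["valid"]]
    individuals = sorted({e.individual_id for e in calls} | set(valid["individual_id"].unique())
                         | set(session.individuals))

    # tracked[i, k]: individual i has a valid fix within +-1 s of t_grid[k]
    tracked = np.zeros((len(individuals), n), dtype=bool)
    for i, ind in enumerate(individuals):
        ts = valid.loc[valid["individual_id"] == ind, "t"].to_numpy()
        if len(ts):
            lo = np.searchsorted(ts, t_grid - 1.0, side="left")
            hi = np.searchsorted(ts, t_grid + 1.0, side="right")
            tracked[i] = hi > lo

    n_tracked = tracked.sum(axis=0)
    reasons[n_tracked < min_tracked] |= TOO_FEW_TRACKED

    # foraging: per tracked individual, a cc onset within (t - lookback, t]
    foraging = np.zeros((len(individuals), n), dtype=bool)
    for i, ind in enumerate(individuals):
        onsets = np.sort([e.t_start for e in calls if e.individual_id == ind and e.category == "cc"])
        if len(onsets):
            lo = np.searchsorted(onsets, t_grid - lookback_s, side="right")
            hi = np.searchsorted(onsets, t_grid, side="right")
            foraging[i] = hi > lo
    n_foraging = (foraging & tracked).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.divide(n_foraging, n_tracked, out=np.zeros(n), where=n_tracked > 0)
    reasons[(frac < foraging_frac) | (n_tracked == 0)] |= NOT_FORAGING

    alarm_onsets = np.sort([e.t_start for e in calls if e.category == "al"])
    if len(alarm_onsets):
        lo = np.searchsorted(alarm_onsets, t_grid - lookback_s, side="right")
        hi = np.searchsorted(alarm_onsets, t_grid, side="right")
        reasons[hi > lo] |= RECENT_ALARM

    return ContextMask(t_grid=t_grid, reasons=reasons)
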