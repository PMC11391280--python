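"""Ground-truth simulator: cohesive group movement plus two calling modes.

The generator produces the kind of dataset a full-group collar deployment
yields — 1 Hz planar trajectories for a cohesive foraging group and
per-individual call streams — under two contrasting generative regimes:

* **broadcast** — each individual runs an independent self-exciting
  (Hawkes-type) point process: a Poisson baseline whose events spawn
  same-individual "burst" offspring with exponentially distributed delays.
  There are no cross-individual terms, so any apparent coordination is
  incidental.  Optionally the baseline is gated up when the individual moves
  faster than a speed threshold (fast-travel calling).
* **exchange** — independent Poisson baselines plus antiphonal responses:
  each emitted call elicits, with probability ``p_resp``, a reply from one
  in-range neighbour (sampled with distance-decay weights) after a lognormal
  latency (~0.4 s by default).  Replies can themselves be answered; because
  at most one responder is recruited per call, the branching ratio is exactly
  ``p_resp`` < 1 and the cascade is always subcritical.

Every triggered call's parent and latency are recorded as ground truth, so
the analysis stages can be validated against known interaction structure.
Identical config + seed give bit-identical output.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .events_io import CallEvent, Session, SyncPing

FORAGE, RUN = 0, 1


class MovementConfig(BaseModel):
    """Correlated random walk with centroid attraction and a 2-state gait."""

    attraction_strength: float = Field(0.10, ge=0)
    persistence: float = Field(0.8, ge=0, le=1)
    base_speed: float = Field(5.0, ge=0, description="foraging speed, m/min")
    run_prob: float = Field(0.0, ge=0, le=1, description="per-second P(forage->run)")
    run_exit_prob: float = Field(0.1, ge=0, le=1, description="per-second P(run->forage)")
    run_speed: float = Field(25.0, ge=0, description="running speed, m/min")
    init_spread_m: float = Field(12.0, gt=0)


class BroadcastConfig(BaseModel):
    """Per-individual self-exciting call stream (no cross-individual terms)."""

    base_rate: float = Field(0.04, ge=0, description="baseline calls/s per individual")
    self_excitation_weight: float = Field(0.5, ge=0, lt=1, description="expected burst offspring per call")
    self_decay_s: float = Field(1.0, gt=0, description="mean offspring delay, s")
    speed_gate: float | None = Field(None, description="m/min; above it baseline is multiplied by speed_gain")
    speed_gain: float = Field(5.0, ge=0)
    category: str = "sn"


class ExchangeConfig(BaseModel):
    """Neighbour-triggered antiphonal responses on top of Poisson baselines."""

    base_rate: float = Field(0.1, ge=0, description="baseline calls/s per individual")
    p_resp: float = Field(0.5, ge=0, le=1, description="response probability per call")
    latency_mean_s: float = Field(0.4, gt=0)
    latency_sd_s: float = Field(0.15, gt=0)
    response_radius_m: float = Field(10.0, gt=0)
    distance_decay: str = Field("hard", pattern="^(hard|exponential)$")
    decay_scale_m: float = Field(5.0, gt=0, description="e-folding scale for the exponential variant")
    juvenile_rate_multiplier: float = Field(1.0, ge=0)
    age_response_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "adult->adult": 1.0, "adult->juvenile": 1.0,
            "juvenile->adult": 1.0, "juvenile->juvenile": 1.0,
        },
        description="multiplier on response weight, keyed 'callerAge->responderAge'",
    )
    category: str = "cc"


class SimConfig(BaseModel):
    """Full simulation configuration; all randomness derives from ``seed``."""

    n_individuals: int = Field(10, ge=1)
    n_juveniles: int = Field(0, ge=0, description="tail individuals carry no GPS")
    session_s: float = Field(3600.0, gt=0)
    step_hz: float = Field(1.0, gt=0)
    call_duration_s: float = Field(0.1, gt=0)
    group_id: str = "G1"
    session_date: str = "2019-07-01"
    movement: MovementConfig = Field(default_factory=MovementConfig)
    broadcast: BroadcastConfig = Field(default_factory=BroadcastConfig)
    exchange: ExchangeConfig = Field(default_factory=ExchangeConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.n_juveniles >= self.n_individuals:
            raise ValueError("n_juveniles must be < n_individuals")
        return self

    def individual_ids(self) -> list[str]:
        return [f"ind{i:02d}" for i in range(self.n_individuals)]

    def age_of(self, individual_id: str) -> str:
        i = int(individual_id[3:])
        return "juvenile" if i >= self.n_individuals - self.n_juveniles else "adult"


@dataclass
class GroundTruth:
    """Trigger links, latencies, per-individual base rates and gait states."""

    triggers: pd.DataFrame  # event_id, trigger_event_id ('' if spontaneous), true_latency_s
    base_rates: dict[str, float]
    movement_states: pd.DataFrame  # individual_id, t, state ('forage'|'run')

    def triggered_fraction(self) -> float:
        if len(self.triggers) == 0:
            return 0.0
        return float((self.triggers["trigger_event_id"] != "").mean())


@dataclass
class SimulatedSession:
    calls: pd.DataFrame          # documented calls schema
    gps: pd.DataFrame            # documented gps schema, GPS-bearing individuals only
    trajectories: pd.DataFrame   # true positions for ALL individuals (incl. juveniles)
    truth: GroundTruth
    session: Session
    config: SimConfig


# ---------------------------------------------------------------------------
# movement


def simulate_group_movement(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate cohesive 1 Hz group trajectories for every individual.

    Each animal follows a correlated random walk whose step direction blends
    a persistent heading with attraction toward the group centroid; a
    two-state Markov chain switches between foraging and running speeds.
    Returns a long frame (individual_id, t, x, y, state); deterministic for
    a given config (the seed is ``config.seed`` unless an rng is passed).
    """
    mv = config.movement
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_individuals
    dt = 1.0 / config.step_hz
    n_steps = int(round(config.session_s * config.step_hz))

    theta0 = rng.uniform(0, 2 * np.pi, size=n)
    r0 = mv.init_spread_m * np.sqrt(rng.uniform(0, 1, size=n))
    pos = np.stack([r0 * np.cos(theta0), r0 * np.sin(theta0)], axis=1)
    heading = rng.uniform(0, 2 * np.pi, size=n)
    state = np.zeros(n, dtype=int)
    heading_sd = (1.0 - mv.persistence) * np.pi

    w = mv.attraction_strength / (1.0 + mv.attraction_strength)
    xs = np.empty((n, n_steps + 1))
    ys = np.empty((n, n_steps + 1))
    states = np.empty((n, n_steps + 1), dtype=int)
    xs[:, 0], ys[:, 0] = pos[:, 0], pos[:, 1]
    states[:, 0] = state

    for k in range(1, n_steps + 1):
        u = rng.uniform(size=n)
        state = np.where(state == FORAGE,
                         np.where(u < mv.run_prob, RUN, FORAGE),
                         np.where(u < mv.run_exit_prob, FORAGE, RUN))
        speed = np.where(state == RUN, mv.run_speed, mv.base_speed) / 60.0  # m/s
        heading = heading + rng.normal(0, heading_sd, size=n)
        hvec = np.stack([np.cos(heading), np.sin(heading)], axis=1)
        centroid = pos.mean(axis=0)
        to_c = centroid[None, :] - pos
        norm = np.linalg.norm(to_c, axis=1, keepdims=True)
        cvec = np.divide(to_c, norm, out=np.zeros_like(to_c), where=norm > 1e-12)
        direction = (1 - w) * hvec + w * cvec
        dnorm = np.linalg.norm(direction, axis=1, keepdims=True)
        direction = np.divide(direction, dnorm, out=hvec.copy(), where=dnorm > 1e-12)
        pos = pos + direction * (speed * dt)[:, None]
        xs[:, k], ys[:, k] = pos[:, 0], pos[:, 1]
        states[:, k] = state

    t_grid = np.arange(n_steps + 1) * dt
    ids = config.individual_ids()
    frames = [
        pd.DataFrame({
            "individual_id": ids[i], "t": t_grid, "x": xs[i], "y": ys[i],
            "state": np.where(states[i] == RUN, "run", "forage"),
        })
        for i in range(n)
    ]
    return pd.concat(frames, ignore_index=True)


def _speed_m_min(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Per-second step speed in m/min (first element repeats the second)."""
    step = np.hypot(np.diff(xs), np.diff(ys)) * 60.0
    return np.concatenate([step[:1], step]) if len(step) else np.zeros(1)


# ---------------------------------------------------------------------------
# calling


def simulate_calls(
    trajectories: pd.DataFrame,
    config: SimConfig,
    mode: str,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-individual call streams on top of the trajectories.

    ``mode`` selects the generative regime (see module docstring).  Returns a
    calls frame in the documented schema plus a :class:`GroundTruth` with one
    trigger row per call.
    """
    if mode not in ("broadcast", "exchange"):
        raise ValueError(f"mode must be 'broadcast' or 'exchange', got {mode!r}")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    ids = config.individual_ids()
    T = config.session_s

    pos_x, pos_y, n_steps = _position_arrays(trajectories, ids)

    raw: list[tuple[float, str, str, float]] = []  # (t, individual, parent_key, latency)
    base_rates: dict[str, float] = {}

    if mode == "broadcast":
        bc = config.broadcast
        for ind in ids:
            rate = bc.base_rate
            base_rates[ind] = rate
            sub = trajectories[trajectories["individual_id"] == ind]
            speeds = _speed_m_min(sub["x"].to_numpy(), sub["y"].to_numpy())
            events = _simulate_hawkes_stream(
                rate, bc.self_excitation_weight, bc.self_decay_s, T, rng,
                speeds=speeds, speed_gate=bc.speed_gate, speed_gain=bc.speed_gain,
            )
            raw.extend(
                (t, ind, None if parent_t is None else (parent_t, ind), lat)
                for t, parent_t, lat in events
            )
        category = bc.category
    else:
        ex = config.exchange
        for ind in ids:
            rate = ex.base_rate * (ex.juvenile_rate_multiplier if config.age_of(ind) == "juvenile" else 1.0)
            base_rates[ind] = rate
        raw = _simulate_exchange_streams(config, ids, base_rates, pos_x, pos_y, n_steps, T, rng)
        category = ex.category

    raw.sort(key=lambda r: (r[0], r[1]))
    key_to_id = {}
    rows, trig_rows = [], []
    for i, (t, ind, parent_key, lat) in enumerate(raw):
        eid = f"c{i:06d}"
        key_to_id[(t, ind)] = eid
        rows.append({
            "event_id": eid, "individual_id": ind, "group_id": config.group_id,
            "session_date": config.session_date, "t_start": t,
            "t_end": min(t + config.call_duration_s, T),
            "category": category, "focal": True,
            "age_class": config.age_of(ind), "n_notes": 1,
        })
        trig_rows.append({"event_id": eid, "parent_key": parent_key, "true_latency_s": lat})

    calls = pd.DataFrame(rows, columns=[
        "event_id", "individual_id", "group_id", "session_date", "t_start", "t_end",
        "category", "focal", "age_class", "n_notes"])
    triggers = pd.DataFrame({
        "event_id": [r["event_id"] for r in trig_rows],
        "trigger_event_id": [key_to_id.get(r["parent_key"], "") if r["parent_key"] else ""
                             for r in trig_rows],
        "true_latency_s": [r["true_latency_s"] for r in trig_rows],
    })
    states = trajectories[["individual_id", "t", "state"]].copy()
    return calls, GroundTruth(triggers=triggers, base_rates=base_rates, movement_states=states)


def _position_arrays(trajectories: pd.DataFrame, ids: list[str]):
    n_steps = int(trajectories.groupby("individual_id")["t"].size().min())
    pos_x = np.empty((len(ids), n_steps))
    pos_y = np.empty((len(ids), n_steps))
    for i, ind in enumerate(ids):
        sub = trajectories[trajectories["individual_id"] == ind].sort_values("t")
        pos_x[i] = sub["x"].to_numpy()[:n_steps]
        pos_y[i] = sub["y"].to_numpy()[:n_steps]
    return pos_x, pos_y, n_steps


def _simulate_hawkes_stream(base_rate, weight, decay_s, T, rng,
                            *, speeds=None, speed_gate=None, speed_gain=1.0):
    """One self-exciting stream via the cluster (branching) construction.

    Returns [(t, parent_t_or_None, latency)] for a single individual;
    immigrants are thinned against the speed gate.
    """
    gated = speed_gate is not None and speeds is not None
    lam_max = base_rate * (max(1.0, speed_gain) if gated else 1.0)
    n_imm = rng.poisson(lam_max * T)
    t_imm = np.sort(rng.uniform(0, T, size=n_imm))
    if gated and n_imm:
        idx = np.clip(t_imm.astype(int), 0, len(speeds) - 1)
        local = base_rate * np.where(speeds[idx] > speed_gate, speed_gain, 1.0)
        t_imm = t_imm[rng.uniform(size=n_imm) * lam_max < local]

    events: list[tuple[float, float | None, float]] = []
    queue: list[tuple[float, float | None]] = [(float(t), None) for t in t_imm]
    while queue:
        t, parent_t = queue.pop()
        events.append((t, parent_t, 0.0 if parent_t is None else t - parent_t))
        for _ in range(rng.poisson(weight)):
            delay = rng.exponential(decay_s)
            if t + delay < T:
                queue.append((float(t + delay), t))
    return events


def _simulate_exchange_streams(config, ids, base_rates, pos_x, pos_y, n_steps, T, rng):
    """Cross-individual antiphonal cascade, processed in time order.

    Each call recruits at most one responder: among neighbours within
    ``response_radius_m`` of the caller at call time, one is drawn with
    probability p_resp·min(1, Σ w_j), with per-neighbour weights w_j =
    decay(d)·age_weight.  Branching ratio <= p_resp, hence subcritical.
    """
    ex = config.exchange
    if ex.p_resp >= 1.0:
        raise ValueError("supercritical exchange cascade: p_resp must be < 1")
    ages = {ind: config.age_of(ind) for ind in ids}
    idx_of = {ind: i for i, ind in enumerate(ids)}

    heap: list[tuple[float, int, str, tuple | None, float]] = []
    counter = itertools.count()
    for ind in ids:
        n_base = rng.poisson(base_rates[ind] * T)
        for t in rng.uniform(0, T, size=n_base):
            heapq.heappush(heap, (float(t), next(counter), ind, None, 0.0))

    out: list[tuple[float, str, tuple | None, float]] = []
    while heap:
        t, _, ind, parent, lat = heapq.heappop(heap)
        out.append((t, ind, parent, lat))
        k = min(int(round(t)), n_steps - 1)
        ci = idx_of[ind]
        dx = pos_x[:, k] - pos_x[ci, k]
        dy = pos_y[:, k] - pos_y[ci, k]
        dist = np.hypot(dx, dy)
        weights = np.zeros(len(ids))
        for j, other in enumerate(ids):
            if other == ind or dist[j] > ex.response_radius_m:
                continue
            w = 1.0 if ex.distance_decay == "hard" else float(np.exp(-dist[j] / ex.decay_scale_m))
            w *= ex.age_response_weights.get(f"{ages[ind]}->{ages[other]}", 1.0)
            weights[j] = w
        total = weights.sum()
        if total <= 0:
            continue
        if rng.uniform() < ex.p_resp * min(1.0, total):
            responder = ids[int(rng.choice(len(ids), p=weights / weights.sum()))]
            latency = _lognormal_latency(ex.latency_mean_s, ex.latency_sd_s, rng)
            t_resp = t + latency
            if t_resp < T:
                heapq.heappush(heap, (float(t_resp), next(counter), responder, (t, ind), latency))
    return out


def _lognormal_latency(mean, sd, rng) -> float:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# clock drift


def simulate_clock_drift(
    events: list[CallEvent],
    drift_ppm_per_device: dict[str, float] | float,
    *,
    ping_interval_s: float = 90.0,
    offset_s: dict[str, float] | float = 0.0,
    t_window: tuple[float, float] | None = None,
) -> tuple[list[CallEvent], list[SyncPing]]:
    """Warp true event times onto per-device clocks and emit a sync-ping table.

    Each device's clock runs at ``1 + ppm*1e-6`` times true rate with a fixed
    offset: ``t_device = offset + (1 + ppm*1e-6) * t_true``.  Pings are
    emitted every ``ping_interval_s`` of true time across the window (default:
    the event span, padded one interval each side).
    """
    devices = sorted({e.individual_id for e in events})

    def _get(table, dev, default):
        return table.get(dev, default) if isinstance(table, dict) else float(table)

    if t_window is None:
        if events:
            lo = min(e.t_start for e in events) - ping_interval_s
            hi = max(e.t_end for e in events) + ping_interval_s
        else:
            lo, hi = 0.0, ping_interval_s
        t_window = (lo, hi)

    ping_times = np.arange(t_window[0], t_window[1] + 1e-9, ping_interval_s)
    pings: list[SyncPing] = []
    warped: list[CallEvent] = []
    for dev in devices:
        rate = 1.0 + _get(drift_ppm_per_device, dev, 0.0) * 1e-6
        off = _get(offset_s, dev, 0.0)
        pings.extend(
            SyncPing(device_id=dev, t_device=off + rate * t, t_true=float(t)) for t in ping_times
        )
    for e in events:
        rate = 1.0 + _get(drift_ppm_per_device, e.individual_id, 0.0) * 1e-6
        off = _get(offset_s, e.individual_id, 0.0)
        warped.append(CallEvent(
            event_id=e.event_id, individual_id=e.individual_id, group_id=e.group_id,
            session_date=e.session_date,
            t_start=off + rate * e.t_start, t_end=off + rate * e.t_end,
            category=e.category, focal=e.focal, age_class=e.age_class, n_notes=e.n_notes,
        ))
    return warped, pings


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_session(config: SimConfig, mode: str) -> SimulatedSession:
    """Simulate movement + calls and package them as analysis-ready tables.

    Juveniles (the last ``n_juveniles`` individuals) appear in the calls and
    the true trajectories but are absent from the emitted GPS table,
    mirroring audio-only collars.
    """
    rng = np.random.default_rng(config.seed)
    traj = simulate_group_movement(config, rng)
    calls, truth = simulate_calls(traj, config, mode, rng)

    gps_ids = [i for i in config.individual_ids() if config.age_of(i) == "adult"]
    gps = traj[traj["individual_id"].isin(gps_ids)][["individual_id", "t", "x", "y"]].copy()
    gps["n_satellites"] = 12
    gps["valid"] = True
    gps = gps.sort_values(["individual_id", "t"], kind="stable").reset_index(drop=True)

    session = Session(
        group_id=config.group_id,
        session_date=config.session_date,
        individuals={i: (config.age_of(i), config.age_of(i) == "adult")
                     for i in config.individual_ids()},
        t_window=(0.0, config.session_s),
    )
    return SimulatedSession(calls=calls, gps=gps, trajectories=traj,
                            truth=truth, session=session, config=config)
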