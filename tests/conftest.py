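import numpy as np
import pandas as pd
import pytest

from vocalmap import synthetic_data as sd
from vocalmap.events_io import CallEvent


@pytest.fixture(scope="session")
def exchange_sim():
    """Small exchange-mode session: strong antiphony, 0.4 s latency, 10 m radius."""
    cfg = sd.SimConfig(
        n_individuals=6, session_s=900.0, seed=11,
        exchange=sd.ExchangeConfig(p_resp=0.7),
    )
    return sd.simulate_session(cfg, "exchange")


@pytest.fixture(scope="session")
def broadcast_sim():
    """Small broadcast-mode session: self-exciting bursts, no cross terms."""
    cfg = sd.SimConfig(
        n_individuals=6, session_s=900.0, seed=11,
        broadcast=sd.BroadcastConfig(base_rate=0.06, self_excitation_weight=0.6),
    )
    return sd.simulate_session(cfg, "broadcast")


def make_calls(rows, group="G1", date="2019-07-01"):
    """Calls frame from (event_id, individual, t_start, t_end, category) tuples;
    longer tuples may append focal, age_class, n_notes."""
    out = []
    for r in rows:
        rec = {
            "event_id": r[0], "individual_id": r[1], "group_id": group,
            "session_date": date, "t_start": float(r[2]), "t_end": float(r[3]),
            "category": r[4], "focal": True, "age_class": "adult", "n_notes": 1,
        }
        if len(r) > 5:
            rec["focal"] = r[5]
        if len(r) > 6:
            rec["age_class"] = r[6]
        if len(r) > 7:
            rec["n_notes"] = r[7]
        out.append(rec)
    return pd.DataFrame(out)


def make_gps(rows):
    """GPS frame from (individual, t, x, y[, n_satellites[, valid]]) tuples."""
    out = []
    for r in rows:
        out.append({
            "individual_id": r[0], "t": float(r[1]), "x": float(r[2]), "y": float(r[3]),
            "n_satellites": int(r[4]) if len(r) > 4 else 12,
            "valid": bool(r[5]) if len(r) > 5 else True,
        })
    return pd.DataFrame(out).sort_values(["individual_id", "t"]).reset_index(drop=True)


def stationary_gps(positions, t0=0.0, t1=600.0):
    """1 Hz stationary tracks: {individual: (x, y)} over [t0, t1]."""
    rows = []
    for ind, (x, y) in positions.items():
        for t in np.arange(t0, t1 + 1.0):
            rows.append((ind, t, x, y))
    return make_gps(rows)


def event(eid, ind, t0, t1, cat="cc", **kw):
    return CallEvent(event_id=eid, individual_id=ind, group_id="G1",
                     session_date="2019-07-01", t_start=t0, t_end=t1,
                     category=cat, **kw)
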