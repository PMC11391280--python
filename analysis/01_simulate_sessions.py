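"""Simulate the two study datasets: exchange-mode cc and broadcast-mode sn.

Writes calls/gps/pings CSVs (plus ground-truth trigger links) for a
close-call session generated as antiphonal exchange (0.4 s latency, 10 m
response radius) and a short-note session generated as speed-gated
self-exciting broadcast, under scratch/data/ (dataset-scale CSVs are working files, not results).
"""

import sys
from pathlib import Path

from vocalmap import events_io
from vocalmap import synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ex_cfg = sd.SimConfig(
        n_individuals=7, session_s=1800.0, seed=SEED,
        exchange=sd.ExchangeConfig(p_resp=0.7, base_rate=0.05))
    ex = sd.simulate_session(ex_cfg, "exchange")

    bc_cfg = sd.SimConfig(
        n_individuals=7, session_s=1800.0, seed=SEED + 1,
        movement=sd.MovementConfig(run_prob=0.01, run_exit_prob=0.05,
                                   base_speed=4.0, run_speed=25.0),
        broadcast=sd.BroadcastConfig(base_rate=0.03, self_excitation_weight=0.5,
                                     speed_gate=10.0, speed_gain=6.0))
    bc = sd.simulate_session(bc_cfg, "broadcast")

    for name, sim in (("exchange", ex), ("broadcast", bc)):
        events = events_io.frame_to_calls(sim.calls)
        # warp onto per-device clocks (200 ppm spread) so preprocessing has
        # real synchronization work to do
        drift = {ind: 100.0 * (i - 3) for i, ind in
                 enumerate(sim.config.individual_ids())}
        warped, pings = sd.simulate_clock_drift(
            events, drift, t_window=(0.0, sim.config.session_s))
        events_io.write_call_events(warped, OUT / f"{name}_calls_device_time.csv")
        events_io.write_gps(events_io.frame_to_gps(sim.gps), OUT / f"{name}_gps.csv")
        events_io.write_sync_pings(pings, OUT / f"{name}_pings.csv")
        sim.truth.triggers.to_csv(OUT / f"{name}_truth.csv", index=False)
        frac = sim.truth.triggered_fraction()
        print(f"{name}: {len(sim.calls)} calls from {sim.config.n_individuals} "
              f"individuals over {sim.config.session_s:.0f} s; "
              f"{frac:.1%} of calls are triggered responses")


if __name__ == "__main__":
    main()
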