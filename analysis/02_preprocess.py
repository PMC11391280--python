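"""Synchronize clocks, clean GPS, merge notes and build context masks.

Reads the device-time call tables written by 01_simulate_sessions.py, maps
them onto UTC through the talking-clock pings, merges quick-succession
notes, quality-filters the GPS and writes the per-second context
eligibility mask used by the call-rate analysis.
"""

import json
from pathlib import Path

from vocalmap import events_io, preprocess

DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
OUT = Path(__file__).resolve().parents[1] / "scratch" / "preprocess"
REPORTS = Path(__file__).resolve().parents[1] / "results" / "preprocess"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    REPORTS.mkdir(parents=True, exist_ok=True)
    for name in ("exchange", "broadcast"):
        warped = events_io.read_call_events(DATA / f"{name}_calls_device_time.csv")
        pings = events_io.read_sync_pings(DATA / f"{name}_pings.csv")
        events = events_io.correct_clock_drift(warped, pings)
        merged = preprocess.merge_notes(events)
        events_io.write_call_events(merged, OUT / f"{name}_calls.csv")

        gps = events_io.gps_to_frame(events_io.read_gps(DATA / f"{name}_gps.csv"))
        cleaned, report = preprocess.clean_gps(gps)
        events_io.write_gps(events_io.frame_to_gps(cleaned), OUT / f"{name}_gps.csv")
        (REPORTS / f"{name}_cleaning_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))

        session = events_io.Session(
            group_id=merged[0].group_id, session_date=merged[0].session_date,
            individuals={e.individual_id: (e.age_class, True) for e in merged},
            t_window=(0.0, 1800.0))
        mask = preprocess.build_context_mask(merged, cleaned, session)
        mask.to_frame().to_csv(OUT / f"{name}_context_mask.csv", index=False)
        print(f"{name}: {len(warped)} notes -> {len(merged)} calls after merging; "
              f"GPS report {report.to_dict()}; "
              f"{mask.eligible.mean():.1%} of seconds context-eligible")


if __name__ == "__main__":
    main()
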