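#!/usr/bin/env python
"""Calcium-transient amplitude distributions across DID epochs.

Detects transients on each day's z-trace, bins event amplitudes per
analysis epoch, normalizes each epoch's distribution to the W1 total
event count, and summarizes AUC and peak location. The expected
dissociation: on both days EtOH1 adds events (AUC above the W1 value of
1); only on the high-E2 day are the added events larger (peak shifted
right). Tables go to results/transients/.
"""

from pathlib import Path

import pandas as pd

from estrocycle import io as eio
from estrocycle.transients import (amplitude_distribution, detect_transients,
                                   segment_epochs, summarize_distribution)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    out = ROOT / "transients"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for day in ("low_e2", "high_e2"):
        session = eio.read_session(ROOT / "sessions", stem=day)
        trace = eio.read_trace(ROOT / "traces" / f"{day}.csv")
        epochs = segment_epochs(session.epoch_schedule)
        events = detect_transients(trace)
        pd.DataFrame([{"time_s": e.time, "amplitude_z": e.amplitude}
                      for e in events]).to_csv(out / f"{day}_events.csv",
                                               index=False)
        w1 = next(e for e in epochs if e.label == "W1")
        for epoch in epochs:
            dist = amplitude_distribution(events, epoch, events, w1)
            s = summarize_distribution(dist)
            rows.append({"day": day, "epoch": epoch.label,
                         "n_events": int(dist.counts.sum()),
                         "auc": s.auc, "peak_z": s.peak_amplitude})
        day_rows = [r for r in rows if r["day"] == day]
        print(f"{day}: " + ", ".join(
            f"{r['epoch']} AUC={r['auc']:.2f} peak={r['peak_z']:.2f}z"
            for r in day_rows))
    pd.DataFrame(rows).to_csv(out / "distribution_summaries.csv",
                              index=False)


if __name__ == "__main__":
    main()
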