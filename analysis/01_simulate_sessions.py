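#!/usr/bin/env python
"""Simulate two modified-DID photometry sessions with known ground truth.

Generates a "low-E2 day" and a "high-E2 day" session over the standard
access schedule (1 h water W1, 2 h 20% EtOH, 30 min water W2). On both
days the transient rate steps up during early alcohol access; on the
high-E2 day the added events are also larger in amplitude. Lick trains
with scheduled drinking bouts are attached. Raw channel tables, lick
lists, epoch sidecars, and the ground truth go to results/sessions/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from estrocycle import io as eio
from estrocycle.photometry import EpochInterval
from estrocycle.synthetic import (PhotometrySimParams, simulate_licks,
                                  simulate_photometry)

OUT = Path(__file__).resolve().parents[1] / "results" / "sessions"

#: scaled acquisition: 1/5 of the hardware rate keeps the full 3.5-h
#: session tractable while preserving the 10.17 Hz effective rate after
#: downsampling by 20
FS_SIM = 1017.25 / 5.0

SCHEDULE = [EpochInterval("W1", 0.0, 3600.0),
            EpochInterval("EtOH", 3600.0, 10800.0),
            EpochInterval("W2", 10800.0, 12600.0)]

# events/min per access period; EtOH carries the drinking-driven increase
RATES = {"W1": 4.0, "EtOH": 8.0, "W2": 4.0}
AMPS_LOW = {"W1": 3.0, "EtOH": 3.0, "W2": 3.0}     # low E2: same amplitude
AMPS_HIGH = {"W1": 3.0, "EtOH": 5.0, "W2": 3.0}    # high E2: larger events

BOUTS_LOW = [(4000.0 + 400 * k, 6) for k in range(8)]
BOUTS_HIGH = [(3900.0 + 250 * k, 10) for k in range(12)]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for day, amps, bout_sched, seed in [("low_e2", AMPS_LOW, BOUTS_LOW, 11),
                                        ("high_e2", AMPS_HIGH, BOUTS_HIGH, 12)]:
        params = PhotometrySimParams(
            duration_s=12600.0, fs=FS_SIM, epoch_schedule=SCHEDULE,
            transient_rate=RATES, transient_amp_mean=amps,
            transient_amp_sd=0.5, noise_sd=0.3, motion_amp=0.6, seed=seed)
        session, truth = simulate_photometry(params)
        session.licks = simulate_licks(bout_sched, seed=seed + 100)
        eio.write_session(session, OUT, stem=day)
        pd.DataFrame({"time_s": truth.transient_times,
                      "amplitude": truth.transient_amps}).to_csv(
            OUT / f"{day}_truth_events.csv", index=False)
        print(f"{day}: {len(session.time_s)} samples, "
              f"{len(truth.transient_times)} true transients, "
              f"{len(session.licks)} licks")


if __name__ == "__main__":
    main()
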