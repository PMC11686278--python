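"""Plain-text readers and writers for every pipeline artifact.

All tables are comma-delimited with headers; timestamp lists are one float
per line; epoch/window schedules are (label, start_s, end_s) sidecars.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import PscStream
from .photometry import EpochInterval, ProcessedTrace, RawSession


def write_session(session: RawSession, out_dir: str | Path,
                  stem: str = "session") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": session.time_s, "f465": session.f465,
                  "f405": session.f405}).to_csv(out / f"{stem}.csv",
                                                index=False)
    np.savetxt(out / f"{stem}_licks.txt", session.licks, fmt="%.6f")
    write_schedule(session.epoch_schedule, out / f"{stem}_epochs.csv")


def read_session(out_dir: str | Path, stem: str = "session",
                 fs: float | None = None, assay: str = "DID") -> RawSession:
    out = Path(out_dir)
    tab = pd.read_csv(out / f"{stem}.csv")
    time_s = tab["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(time_s)))
    licks_path = out / f"{stem}_licks.txt"
    licks = np.atleast_1d(np.loadtxt(licks_path)) \
        if licks_path.stat().st_size else np.empty(0)
    schedule = read_schedule(out / f"{stem}_epochs.csv")
    return RawSession(time_s=time_s, f465=tab["f465"].to_numpy(),
                      f405=tab["f405"].to_numpy(), fs=fs, assay=assay,
                      licks=licks, epoch_schedule=schedule)


def write_schedule(schedule: list[EpochInterval], path: str | Path) -> None:
    pd.DataFrame(
        [{"label": ep.label, "start_s": ep.start_s, "end_s": ep.end_s}
         for ep in schedule]
    ).to_csv(path, index=False)


def read_schedule(path: str | Path) -> list[EpochInterval]:
    tab = pd.read_csv(path)
    return [EpochInterval(str(r.label), float(r.start_s), float(r.end_s))
            for r in tab.itertuples()]


def write_trace(trace: ProcessedTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "z": trace.z}).to_csv(path,
                                                                index=False)
    prov_path = Path(path).with_suffix(".provenance.txt")
    lines = [repr(step) for step in trace.provenance]
    prov_path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path, fs_eff: float | None = None) -> ProcessedTrace:
    tab = pd.read_csv(path)
    t = tab["time_s"].to_numpy()
    if fs_eff is None:
        fs_eff = 1.0 / float(np.median(np.diff(t)))
    return ProcessedTrace(time_s=t, z=tab["z"].to_numpy(), fs_eff=fs_eff)


def write_psc_stream(stream: PscStream, out_dir: str | Path,
                     stem: str = "psc") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": stream.event_times,
                  "amplitude_pA": stream.amplitudes}).to_csv(
        out / f"{stem}.csv", index=False)
    pd.DataFrame(
        [{"label": k, "start_s": v[0], "end_s": v[1]}
         for k, v in stream.windows.items()]
    ).to_csv(out / f"{stem}_windows.csv", index=False)


def read_psc_stream(out_dir: str | Path, stem: str = "psc") -> PscStream:
    out = Path(out_dir)
    tab = pd.read_csv(out / f"{stem}.csv")
    wins = pd.read_csv(out / f"{stem}_windows.csv")
    windows = {str(r.label): (float(r.start_s), float(r.end_s))
               for r in wins.itertuples()}
    return PscStream(event_times=tab["time_s"].to_numpy(),
                     amplitudes=tab["amplitude_pA"].to_numpy(),
                     windows=windows)
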