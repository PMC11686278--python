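"""Lickometer bout detection, epoch summaries, peri-event alignment,
and fluid-intake normalization.

A drinking bout is a greedy cluster of consecutive licks whose inter-lick
interval is at most 1 s, kept only if it contains at least 2 licks and
spans at least 0.5 s. "Motivated" bouts are the subset lasting more than
1 s (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .photometry import EpochInterval, ProcessedTrace


@dataclass
class Bout:
    onset: float
    offset: float
    n_licks: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BoutSummary:
    """Per-epoch bout metrics; ``motivated_n_bouts`` counts bouts whose
    duration strictly exceeds the motivated threshold."""

    epoch_label: str
    n_bouts: int
    motivated_n_bouts: int
    time_in_bout: float
    mean_bout_duration: float


@dataclass
class PeriEventMatrix:
    """Z-trace segments aligned to bout onsets (one row per usable onset)."""

    window: tuple[float, float]
    rows: np.ndarray          # (n_events, n_samples)
    mean_trace: np.ndarray
    rel_time_s: np.ndarray
    n_events: int
    n_dropped: int


@dataclass
class IntakeRecord:
    """Bottle weights for one session, used to compute dose in g/kg."""

    bottle_loss_g: float
    dummy_leak_g: float
    bodyweight_kg: float
    solution: str = "EtOH"    # "EtOH" (20% v/v) or "sucrose" (1% w/v)


ETHANOL_DENSITY_G_PER_ML = 0.789
ETHANOL_VOL_FRACTION = 0.20
SUCROSE_MASS_FRACTION = 0.01
FLUID_DENSITY_G_PER_ML = 1.0  # gram->ml approximation for the mixed fluid


def detect_bouts(licks: np.ndarray, max_ili: float = 1.0,
                 min_licks: int = 2, min_duration: float = 0.5) -> list[Bout]:
    """Greedily cluster lick timestamps into drinking bouts.

    Consecutive licks with inter-lick interval <= ``max_ili`` (inclusive)
    join one cluster; clusters with at least ``min_licks`` licks and span
    of at least ``min_duration`` (inclusive) become bouts.
    """
    licks = np.asarray(licks, dtype=float)
    if len(licks) == 0:
        return []
    if np.any(np.diff(licks) <= 0):
        raise DataError("lick timestamps must be strictly increasing")
    if np.any(licks < 0):
        raise DataError("lick timestamps must be non-negative")
    splits = np.nonzero(np.diff(licks) > max_ili)[0] + 1
    bouts = []
    for cluster in np.split(licks, splits):
        if len(cluster) >= min_licks and cluster[-1] - cluster[0] >= min_duration:
            bouts.append(Bout(onset=float(cluster[0]),
                              offset=float(cluster[-1]),
                              n_licks=int(len(cluster))))
    return bouts


def summarize_bouts(bouts: list[Bout], epoch: EpochInterval,
                    motivated_min_duration: float = 1.0) -> BoutSummary:
    """Summarize the bouts whose onset falls inside ``epoch``.

    Epoch membership is by onset time (half-open interval), so a bout
    straddling an epoch boundary is counted exactly once.
    """
    inside = [b for b in bouts if epoch.contains(b.onset)]
    durations = [b.duration for b in inside]
    return BoutSummary(
        epoch_label=epoch.label,
        n_bouts=len(inside),
        motivated_n_bouts=sum(d > motivated_min_duration for d in durations),
        time_in_bout=float(sum(durations)),
        mean_bout_duration=float(np.mean(durations)) if durations else 0.0,
    )


def peri_event(trace: ProcessedTrace, onsets: np.ndarray,
               window: tuple[float, float] = (0.0, 10.0)) -> PeriEventMatrix:
    """Extract z-trace segments aligned to event onsets.

    Each row is the trace restricted to [onset + window[0],
    onset + window[1]) at the trace's effective sampling rate; onsets whose
    window exceeds the trace support are dropped and counted.
    """
    onsets = np.asarray(onsets, dtype=float)
    w0, w1 = window
    if w1 <= w0:
        raise ParameterError("window must have positive length")
    n_samples = int(round((w1 - w0) * trace.fs_eff))
    t0 = trace.time_s[0]
    rows, n_dropped = [], 0
    for onset in onsets:
        i0 = int(round((onset + w0 - t0) * trace.fs_eff))
        if i0 < 0 or i0 + n_samples > len(trace.z):
            n_dropped += 1
            continue
        rows.append(trace.z[i0: i0 + n_samples])
    if not rows:
        raise DataError("no onset has full trace coverage for the window")
    mat = np.vstack(rows)
    rel = w0 + np.arange(n_samples) / trace.fs_eff
    return PeriEventMatrix(window=(w0, w1), rows=mat,
                           mean_trace=mat.mean(axis=0), rel_time_s=rel,
                           n_events=len(rows), n_dropped=n_dropped)


def normalize_intake(record: IntakeRecord) -> float:
    """Convert bottle weight loss to a bodyweight-normalized dose (g/kg).

    Loss is corrected by the dummy-bottle leak (clamped at zero), converted
    to volume at 1 g/ml, then to grams of solute: 20% v/v ethanol at
    0.789 g/ml, or 1% w/v sucrose.
    """
    if record.bodyweight_kg <= 0:
        raise DataError("bodyweight must be positive")
    if record.bottle_loss_g < 0 or record.dummy_leak_g < 0:
        raise DataError("weights must be non-negative")
    net_ml = max(record.bottle_loss_g - record.dummy_leak_g, 0.0) \
        / FLUID_DENSITY_G_PER_ML
    sol = record.solution.lower()
    if sol == "etoh":
        grams = net_ml * ETHANOL_VOL_FRACTION * ETHANOL_DENSITY_G_PER_ML
    elif sol == "sucrose":
        grams = net_ml * SUCROSE_MASS_FRACTION
    else:
        raise ParameterError(f"unknown solution {record.solution!r}")
    return grams / record.bodyweight_kg
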