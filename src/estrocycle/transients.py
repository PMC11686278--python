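"""Calcium-transient detection and W1-normalized amplitude distributions.

The DID session is segmented into four 30-min analysis epochs (last 30 min
of the first water access W1, first and last 30 min of alcohol access
EtOH1/EtOH2, first 30 min of the second water access W2). Transient events
are local maxima of the z-trace exceeding a robust (MAD-based) noise
threshold. Per-epoch amplitude histograms are divided by the *total* event
count of the reference (W1) epoch, so a pure rate increase raises the area
under the distribution above 1 while leaving its peak location unchanged,
and a pure amplitude increase shifts the peak rightward — the dissociation
the distribution statistics are designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError, DegenerateDataError, ParameterError
from .photometry import EpochInterval, ProcessedTrace

EPOCH_LEN_S = 1800.0  # 30-min analysis epochs


@dataclass
class TransientEvent:
    time: float
    amplitude: float  # z-units, peak minus local baseline


@dataclass
class AmplitudeDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    rate_per_min: np.ndarray
    normalized: np.ndarray
    epoch_label: str
    reference_label: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DistributionSummary:
    auc: float
    peak_amplitude: float


def segment_epochs(schedule: list[EpochInterval]) -> list[EpochInterval]:
    """Derive the four 30-min analysis epochs from the access schedule.

    Requires access periods labeled W1 (>= 30 min), EtOH (>= 60 min) and
    W2 (>= 30 min); returns W1 = last 30 min of W1 access, EtOH1/EtOH2 =
    first/last 30 min of EtOH access, W2 = first 30 min of W2 access.
    """
    access = {ep.label: ep for ep in schedule}
    for label, need in (("W1", EPOCH_LEN_S), ("EtOH", 2 * EPOCH_LEN_S),
                        ("W2", EPOCH_LEN_S)):
        if label not in access:
            raise DataError(f"schedule lacks a {label!r} access period")
        if access[label].duration_s < need:
            raise DataError(
                f"{label} access of {access[label].duration_s:.0f}s shorter "
                f"than required {need:.0f}s"
            )
    w1, et, w2 = access["W1"], access["EtOH"], access["W2"]
    return [
        EpochInterval("W1", w1.end_s - EPOCH_LEN_S, w1.end_s),
        EpochInterval("EtOH1", et.start_s, et.start_s + EPOCH_LEN_S),
        EpochInterval("EtOH2", et.end_s - EPOCH_LEN_S, et.end_s),
        EpochInterval("W2", w2.start_s, w2.start_s + EPOCH_LEN_S),
    ]


def mad_noise_scale(z: np.ndarray) -> float:
    """Robust noise sd estimate: 1.4826 * median absolute deviation.

    Transients occupy a small fraction of samples, so the MAD tracks the
    noise floor where the sample sd would be inflated by the events.
    """
    z = np.asarray(z, dtype=float)
    return 1.4826 * float(np.median(np.abs(z - np.median(z))))


def detect_transients(trace: ProcessedTrace, k_mad: float = 2.5,
                      min_separation_s: float = 1.0,
                      baseline_percentile: float = 10.0,
                      baseline_window_s: float = 5.0) -> list[TransientEvent]:
    """Detect transient peaks on the z-trace.

    Local maxima above ``median + k_mad * MAD-noise`` with prominence of at
    least ``k_mad * MAD-noise`` are kept; the prominence requirement
    suppresses ripple maxima riding on the decay tail of a larger event.
    Peaks closer than ``min_separation_s`` keep only the larger. The
    amplitude is the peak value minus the ``baseline_percentile`` of the
    preceding ``baseline_window_s`` of trace (clipped at the trace start),
    making the measure invariant to adding a constant to the trace.
    """
    if len(trace.z) == 0:
        raise DataError("empty trace")
    if k_mad <= 0:
        raise ParameterError("k_mad must be > 0")
    z = trace.z
    noise = mad_noise_scale(z)
    height = float(np.median(z)) + k_mad * noise
    distance = max(int(round(min_separation_s * trace.fs_eff)), 1)
    peaks, _ = signal.find_peaks(z, height=height, distance=distance,
                                 prominence=k_mad * noise)
    win = max(int(round(baseline_window_s * trace.fs_eff)), 1)
    events = []
    for idx in peaks:
        lo = max(idx - win, 0)
        base = np.percentile(z[lo:idx], baseline_percentile)  # idx >= 1 always
        amp = float(z[idx] - base)
        if amp > 0:
            events.append(TransientEvent(time=float(trace.time_s[idx]),
                                         amplitude=amp))
    return events


def match_events(detected: list[TransientEvent], true_times: np.ndarray,
                 tol_s: float = 0.5,
                 resolvable_gap_s: float | None = None) -> dict[str, float]:
    """Greedily match detected events to ground-truth times within a
    tolerance and report sensitivity and false-discovery rate.

    Each true event consumes at most one detection (nearest in time).
    With ``resolvable_gap_s`` set, sensitivity is computed over resolvable
    true events only — those with no neighboring true event within the gap
    on either side — since the detector's minimum peak separation makes
    closer pairs a single compound event by construction.
    """
    true_all = np.sort(np.asarray(true_times, dtype=float))
    if resolvable_gap_s is not None and len(true_all) > 1:
        gaps = np.diff(true_all)
        keep = (np.concatenate([[True], gaps >= resolvable_gap_s])
                & np.concatenate([gaps >= resolvable_gap_s, [True]]))
        resolvable = true_all[keep]
    else:
        resolvable = true_all
    det_times = np.array([e.time for e in detected])

    def greedy_hits(truth: np.ndarray) -> tuple[int, np.ndarray]:
        used = np.zeros(len(det_times), dtype=bool)
        hits = 0
        for t0 in truth:
            if len(det_times) == 0:
                break
            d = np.abs(det_times - t0)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= tol_s:
                used[j] = True
                hits += 1
        return hits, used

    n_hit, _ = greedy_hits(resolvable)
    # FDR counts a detection as true if it matches *any* true event,
    # including members of unresolvable pairs
    _, used_all = greedy_hits(true_all)
    n_true = len(resolvable)
    n_det = len(det_times)
    sensitivity = n_hit / n_true if n_true else float("nan")
    fdr = (n_det - used_all.sum()) / n_det if n_det else 0.0
    return {"n_true": n_true, "n_detected": n_det, "n_matched": n_hit,
            "sensitivity": sensitivity, "fdr": float(fdr)}


def _epoch_events(events: list[TransientEvent],
                  epoch: EpochInterval) -> list[TransientEvent]:
    return [e for e in events if epoch.contains(e.time)]


def amplitude_distribution(
    events: list[TransientEvent],
    epoch: EpochInterval,
    reference_events: list[TransientEvent],
    reference_epoch: EpochInterval,
    bin_width: float = 0.5,
    amp_range: tuple[float, float] = (0.0, 10.0),
) -> AmplitudeDistribution:
    """Bin an epoch's event amplitudes and normalize by the reference total.

    ``normalized[bin] = count[bin] / (total reference-epoch event count)``;
    the reference epoch's own normalized distribution therefore sums to 1,
    and an epoch with added events has total mass above 1.
    """
    if epoch.duration_s <= 0 or reference_epoch.duration_s <= 0:
        raise ParameterError("epochs must have positive duration")
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    n_ref = len(_epoch_events(reference_events, reference_epoch))
    if n_ref == 0:
        raise DegenerateDataError("reference epoch has zero events")
    edges = np.arange(amp_range[0], amp_range[1] + bin_width / 2, bin_width)
    amps = np.array([e.amplitude for e in _epoch_events(events, epoch)])
    counts, _ = np.histogram(amps, bins=edges)  # half-open bins
    duration_min = epoch.duration_s / 60.0
    return AmplitudeDistribution(
        bin_edges=edges,
        counts=counts,
        rate_per_min=counts / duration_min,
        normalized=counts / n_ref,
        epoch_label=epoch.label,
        reference_label=reference_epoch.label,
    )


def summarize_distribution(dist: AmplitudeDistribution) -> DistributionSummary:
    """AUC (trapezoid over bin centers) and peak location of a distribution.

    Argmax ties break toward the lower amplitude bin.
    """
    if not np.any(dist.normalized > 0):
        raise DegenerateDataError("all-zero distribution")
    centers = dist.bin_centers
    auc = float(np.trapezoid(dist.normalized, centers))
    peak = float(centers[int(np.argmax(dist.normalized))])
    return DistributionSummary(auc=auc, peak_amplitude=peak)
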