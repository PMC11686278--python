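"""Slice-pharmacology metrics on spontaneous PSC event streams.

Recordings are annotated with three ordered windows (baseline, drug
wash-on, washout). Per-minute frequency or amplitude is expressed as
percent of the baseline-window mean, and a cell is called a responder if
the wash-on mean deviates from 100% by at least 15 percentage points OR
any single one-minute bin deviates by at least 50 points (both inclusive).
Cells whose access resistance changes by more than 20% are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np

from .errors import DataError, DegenerateDataError, ParameterError

MEAN_RULE_PCT = 15.0     # threshold on |mean wash-on % - 100|
MINUTE_RULE_PCT = 50.0   # threshold on any single bin's |% - 100|


@dataclass
class PscStream:
    """Time-stamped postsynaptic-current events with window annotations."""

    event_times: np.ndarray
    amplitudes: np.ndarray
    windows: dict[str, tuple[float, float]]
    polarity: str = "excitatory"

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.event_times) != len(self.amplitudes):
            raise DataError("event times and amplitudes must align")
        if np.any(np.diff(self.event_times) < 0):
            raise DataError("event times must be sorted")
        if np.any(self.amplitudes <= 0):
            raise DataError("amplitudes are magnitudes and must be positive")


@dataclass
class EphysMetrics:
    frequency_hz: float
    mean_amplitude_pa: float
    synaptic_drive: float          # frequency x amplitude (Hz * pA)
    amplitude_defined: bool = True


@dataclass
class Timecourse:
    bin_edges: np.ndarray
    pct_baseline: np.ndarray
    metric: str
    wash_mask: np.ndarray          # bins whose start lies in the wash window
    baseline_mean: float


@dataclass
class ResponderCall:
    category: str                  # increase | decrease | no_change
    max_delta_pct: float           # signed wash-on deviation of largest |.|
    triggering_rule: str           # mean15 | minute50 | none


@dataclass
class CellQC:
    access_resistance_series: np.ndarray
    included: bool
    max_rel_change: float


def event_metrics(stream: PscStream,
                  window: tuple[float, float]) -> EphysMetrics:
    """Frequency, mean amplitude, and synaptic drive within a window."""
    start, end = window
    if end <= start:
        raise ParameterError("window must have positive duration")
    mask = (stream.event_times >= start) & (stream.event_times < end)
    n = int(mask.sum())
    freq = n / (end - start)
    if n == 0:
        return EphysMetrics(frequency_hz=0.0, mean_amplitude_pa=float("nan"),
                            synaptic_drive=0.0, amplitude_defined=False)
    amp = float(stream.amplitudes[mask].mean())
    return EphysMetrics(frequency_hz=freq, mean_amplitude_pa=amp,
                        synaptic_drive=freq * amp)


def percent_baseline_timecourse(stream: PscStream, metric: str = "frequency",
                                bin_s: float = 60.0) -> Timecourse:
    """Binned metric expressed as percent of the baseline-window mean.

    Bins tile the recording from the baseline start to the washout end.
    Frequency bins with no events are 0%; amplitude bins with no events
    are NaN (no measurable amplitude).
    """
    if metric not in ("frequency", "amplitude"):
        raise ParameterError("metric must be 'frequency' or 'amplitude'")
    if bin_s <= 0:
        raise ParameterError("bin length must be > 0")
    b = stream.windows["baseline"]
    o = stream.windows["washout"]
    w = stream.windows["wash"]
    if (b[1] - b[0]) < 2 * bin_s:
        raise ParameterError("baseline window must cover >= 2 bins")
    edges = np.arange(b[0], o[1] + bin_s / 2, bin_s)
    values = np.empty(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        m = event_metrics(stream, (lo, hi))
        if metric == "frequency":
            values[i] = m.frequency_hz
        else:
            values[i] = m.mean_amplitude_pa if m.amplitude_defined else np.nan
    starts = edges[:-1]
    base_mask = (starts >= b[0]) & (starts < b[1])
    base_vals = values[base_mask]
    base_mean = float(np.nanmean(base_vals)) if len(base_vals) else np.nan
    if not np.isfinite(base_mean) or base_mean == 0:
        raise DegenerateDataError("baseline metric is zero or undefined")
    pct = values / base_mean * 100.0
    wash_mask = (starts >= w[0]) & (starts < w[1])
    return Timecourse(bin_edges=edges, pct_baseline=pct, metric=metric,
                      wash_mask=wash_mask, baseline_mean=base_mean)


def classify_responder(tc: Timecourse) -> ResponderCall:
    """Apply the two-rule responder classification to a time course.

    Rule ``mean15`` fires when the mean wash-on percent deviates from 100
    by >= 15 (inclusive); rule ``minute50`` fires when any single wash-on
    bin deviates by >= 50 (inclusive). The category's direction follows the
    firing criterion with the larger absolute deviation.
    """
    wash = tc.pct_baseline[tc.wash_mask]
    wash = wash[np.isfinite(wash)]
    if len(wash) == 0:
        raise DataError("no finite wash-on bins to classify")
    mean_delta = float(np.mean(wash) - 100.0)
    bin_deltas = wash - 100.0
    max_bin_delta = float(bin_deltas[np.argmax(np.abs(bin_deltas))])
    mean_fires = abs(mean_delta) >= MEAN_RULE_PCT
    minute_fires = abs(max_bin_delta) >= MINUTE_RULE_PCT
    if not mean_fires and not minute_fires:
        return ResponderCall(category="no_change",
                             max_delta_pct=max_bin_delta,
                             triggering_rule="none")
    if mean_fires and (not minute_fires
                       or abs(mean_delta) >= abs(max_bin_delta)):
        delta, rule = mean_delta, "mean15"
    else:
        delta, rule = max_bin_delta, "minute50"
    return ResponderCall(category="increase" if delta > 0 else "decrease",
                         max_delta_pct=max_bin_delta,
                         triggering_rule=rule)


def qc_access(series: np.ndarray, threshold: float = 0.20) -> CellQC:
    """Flag a cell for exclusion if access resistance drifts > 20%.

    The reference is the first measurement; change strictly above the
    threshold excludes the cell.
    """
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        raise DataError("empty access-resistance series")
    if np.any(series <= 0):
        raise DataError("access resistance must be positive")
    rel = float(np.max(np.abs(series - series[0])) / series[0])
    return CellQC(access_resistance_series=series,
                  included=rel <= threshold, max_rel_change=rel)


def cohort_response_summary(calls: list[ResponderCall]) -> dict[str, float]:
    """Fraction of cells per responder category (fractions sum to 1)."""
    if not calls:
        raise DataError("empty list of responder calls")
    counts = Counter(c.category for c in calls)
    n = len(calls)
    return {cat: counts.get(cat, 0) / n
            for cat in ("increase", "decrease", "no_change")}
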