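"""Synthetic-data generators for every pipeline input.

Each generator draws from one explicitly seeded ``numpy`` Generator and
returns the ground truth alongside the data, so every downstream stage can
be tested against known answers without any external recordings.

What is emulated (and what is not) is documented in ``docs/methods.md``:
GCaMP transients are Poisson-timed with lognormal amplitudes and an
instantaneous-rise / exponential-decay kernel; motion is a slow shared
artifact added to both channels; photobleaching is a single exponential;
lick trains are bout-structured; PSC streams are piecewise-homogeneous
Poisson processes with a rate step during drug wash-on; calibration ratios
sit on a line with proportional noise; count matrices are Bernoulli-gated
sparse counts with specified per-gene expression probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, sparse

from .calibration import CalLevel
from .ephys import PscStream
from .errors import ParameterError
from .expression import CountMatrix
from .photometry import NOMINAL_FS, EpochInterval, RawSession

__all__ = [
    "PhotometrySimParams", "GroundTruth", "simulate_photometry",
    "simulate_licks", "simulate_psc_stream", "simulate_calibration",
    "simulate_counts",
]


@dataclass
class PhotometrySimParams:
    """Generative settings for a two-channel photometry session.

    ``transient_rate`` is events/min, either one number for the whole
    session or a mapping from epoch label to rate (time outside any labeled
    epoch is then event-free). ``motion_amp`` scales a shared slow artifact
    added to both channels; the signal channel receives it with gain
    ``motion_gain_465``.
    """

    duration_s: float = 600.0
    fs: float = NOMINAL_FS
    transient_rate: float | dict[str, float] = 6.0
    transient_amp_mean: float | dict[str, float] = 3.0
    transient_amp_sd: float = 1.0
    decay_tau: float = 1.5
    motion_amp: float = 0.5
    motion_gain_465: float = 0.8
    bleach_tau: float = 1500.0
    bleach_frac: float = 0.15
    noise_sd: float = 0.3
    baseline_465: float = 100.0
    baseline_405: float = 80.0
    epoch_schedule: list[EpochInterval] = field(default_factory=list)
    #: explicit event times override the Poisson draw (for constructed tests)
    transient_times: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        rates = (self.transient_rate.values()
                 if isinstance(self.transient_rate, dict)
                 else [self.transient_rate])
        if any(r < 0 for r in rates):
            raise ParameterError("transient rates must be >= 0")
        for name in ("transient_amp_sd", "decay_tau", "motion_amp",
                     "bleach_tau", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        last_end = 0.0
        for ep in self.epoch_schedule:
            if ep.start_s < last_end or ep.end_s > self.duration_s:
                raise ParameterError(
                    "epoch intervals must be disjoint, ordered, and within "
                    "[0, duration_s)"
                )
            last_end = ep.end_s


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    transient_times: np.ndarray
    transient_amps: np.ndarray
    motion_trace: np.ndarray
    bout_schedule: list[tuple[float, np.ndarray]] = field(default_factory=list)


def _poisson_times(rng: np.random.Generator, rate_per_min: float,
                   start: float, end: float) -> np.ndarray:
    """Homogeneous Poisson event times on [start, end)."""
    if rate_per_min <= 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate_per_min / 60.0 * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


def _lognormal_amps(rng: np.random.Generator, n: int,
                    mean: float, sd: float) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if mean <= 0:
        return np.zeros(n)
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _smooth_motion(rng: np.random.Generator, n: int, fs: float,
                   amp: float, cutoff_hz: float = 0.5) -> np.ndarray:
    """Slow shared artifact: lowpassed white noise rescaled to sd = amp."""
    if amp == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = signal.butter(2, min(cutoff_hz, 0.45 * fs), btype="low",
                        fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, white)
    sd = slow.std()
    if sd == 0:
        return np.zeros(n)
    return slow / sd * amp


def simulate_photometry(
    params: PhotometrySimParams,
) -> tuple[RawSession, GroundTruth]:
    """Simulate an aligned 465/405 nm session with known ground truth.

    The signal channel is bleach + transients + gain*motion + noise; the
    isosbestic channel is bleach' + motion + noise', with the *identical*
    motion trace in both — the structure the linear-fit correction exploits.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(params.duration_s * params.fs)
    t = np.arange(n) / params.fs

    def amp_mean_at(t0: float) -> float:
        if not isinstance(params.transient_amp_mean, dict):
            return params.transient_amp_mean
        for ep in params.epoch_schedule:
            if ep.contains(t0):
                return params.transient_amp_mean.get(ep.label, 0.0)
        return 0.0

    # event times: explicit, homogeneous, or per labeled epoch
    if params.transient_times is not None:
        times = np.sort(np.asarray(params.transient_times, dtype=float))
        if len(times) and (times[0] < 0 or times[-1] >= params.duration_s):
            raise ParameterError("explicit transient times outside session")
    elif isinstance(params.transient_rate, dict):
        pieces = [
            _poisson_times(rng, params.transient_rate.get(ep.label, 0.0),
                           ep.start_s, ep.end_s)
            for ep in params.epoch_schedule
        ]
        times = np.sort(np.concatenate(pieces)) if pieces else np.empty(0)
    else:
        times = _poisson_times(rng, params.transient_rate, 0.0,
                               params.duration_s)
    amps = np.concatenate([
        _lognormal_amps(rng, 1, amp_mean_at(t0), params.transient_amp_sd)
        for t0 in times
    ]) if len(times) else np.empty(0)

    transients = np.zeros(n)
    kernel_len = int(min(10.0 * params.decay_tau, params.duration_s) * params.fs)
    if kernel_len > 0 and len(times):
        kernel_t = np.arange(kernel_len) / params.fs
        kernel = np.exp(-kernel_t / params.decay_tau) if params.decay_tau > 0 \
            else np.concatenate([[1.0], np.zeros(kernel_len - 1)])
        for t0, a in zip(times, amps):
            i0 = int(np.floor(t0 * params.fs))
            i1 = min(i0 + kernel_len, n)
            transients[i0:i1] += a * kernel[: i1 - i0]

    motion = _smooth_motion(rng, n, params.fs, params.motion_amp)

    def bleach(baseline: float) -> np.ndarray:
        if params.bleach_frac == 0 or params.bleach_tau == 0:
            return np.full(n, baseline)
        return baseline * (1.0 - params.bleach_frac
                           * (1.0 - np.exp(-t / params.bleach_tau)))

    f465 = (bleach(params.baseline_465) + transients
            + params.motion_gain_465 * motion
            + rng.normal(0.0, params.noise_sd, size=n))
    f405 = (bleach(params.baseline_405) + motion
            + rng.normal(0.0, params.noise_sd, size=n))

    session = RawSession(time_s=t, f465=f465, f405=f405, fs=params.fs,
                         assay="DID", epoch_schedule=list(params.epoch_schedule))
    truth = GroundTruth(transient_times=times, transient_amps=amps,
                        motion_trace=motion)
    return session, truth


def simulate_licks(bout_schedule: list[tuple[float, int]],
                   seed: int = 0) -> np.ndarray:
    """Generate a lick-timestamp train organized in scheduled bouts.

    ``bout_schedule`` is a list of (onset_s, n_licks). Within a bout,
    inter-lick intervals are drawn uniformly from
    [max(0.15, 0.5/(n_licks-1)), 0.95] s, which guarantees every scheduled
    bout satisfies the detection rule (ILI <= 1 s, span >= 0.5 s); between
    bouts the gap exceeds 1 s, so the bout detector recovers the schedule
    exactly. Overlap is rejected conservatively using the maximal possible
    span (n_licks - 1) * 0.95 s plus the 1 s separating gap.
    """
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    prev_onset, prev_n = None, None
    for onset, n_licks in bout_schedule:
        if n_licks < 2:
            raise ParameterError("each scheduled bout needs >= 2 licks")
        if onset < 0:
            raise ParameterError("bout onsets must be >= 0")
        if prev_onset is not None:
            min_gap = (prev_n - 1) * 0.95 + 1.0
            if onset <= prev_onset + min_gap:
                raise ParameterError(
                    f"bouts at {prev_onset}s and {onset}s may overlap "
                    f"(need gap > {min_gap:.2f}s)"
                )
        lo = max(0.15, 0.5 / (n_licks - 1))
        ilis = rng.uniform(lo, 0.95, size=n_licks - 1)
        out.append(onset + np.concatenate([[0.0], np.cumsum(ilis)]))
        prev_onset, prev_n = onset, n_licks
    return np.concatenate(out) if out else np.empty(0)


def simulate_psc_stream(
    baseline_rate: float,
    amp_mean: float,
    wash_multiplier: float,
    windows: dict[str, tuple[float, float]],
    seed: int = 0,
    amp_cv: float = 0.35,
    wash_amp_multiplier: float = 1.0,
) -> PscStream:
    """Simulate a spontaneous PSC event stream with a drug wash-on step.

    Event times follow a Poisson process at ``baseline_rate`` Hz outside
    the wash window and ``baseline_rate * wash_multiplier`` inside it;
    amplitudes are i.i.d. gamma (mean ``amp_mean`` pA, CV ``amp_cv``),
    scaled by ``wash_amp_multiplier`` during the wash.
    """
    if baseline_rate < 0 or wash_multiplier < 0:
        raise ParameterError("rates and multipliers must be >= 0")
    for key in ("baseline", "wash", "washout"):
        if key not in windows:
            raise ParameterError(f"windows must define {key!r}")
    b, w, o = windows["baseline"], windows["wash"], windows["washout"]
    if not (b[0] < b[1] <= w[0] < w[1] <= o[0] < o[1]):
        raise ParameterError("windows must be ordered baseline < wash < washout")

    rng = np.random.default_rng(seed)
    # piecewise-constant rate over the full recorded span
    segments = [(b[0], w[0], baseline_rate),
                (w[0], w[1], baseline_rate * wash_multiplier),
                (w[1], o[1], baseline_rate)]
    times_parts, amps_parts = [], []
    for start, end, rate in segments:
        seg_times = _poisson_times(rng, rate * 60.0, start, end)
        if len(seg_times) == 0:
            continue
        shape = 1.0 / amp_cv**2 if amp_cv > 0 else None
        if shape is None:
            seg_amps = np.full(len(seg_times), amp_mean)
        else:
            seg_amps = rng.gamma(shape, amp_mean / shape, size=len(seg_times))
        if w[0] <= start < w[1]:
            seg_amps = seg_amps * wash_amp_multiplier
        times_parts.append(seg_times)
        amps_parts.append(seg_amps)
    if times_parts:
        times = np.concatenate(times_parts)
        amps = np.concatenate(amps_parts)
        order = np.argsort(times)
        times, amps = times[order], amps[order]
    else:
        times, amps = np.empty(0), np.empty(0)
    return PscStream(event_times=times, amplitudes=amps,
                     windows={"baseline": b, "wash": w, "washout": o})


def simulate_calibration(
    true_slope: float,
    true_intercept: float,
    levels: list[float],
    replicates: int = 3,
    cv: float = 0.05,
    seed: int = 0,
) -> list[CalLevel]:
    """Simulate replicate peak-area ratios on a calibration line.

    Each replicate ratio is Normal(slope*C + intercept, cv * mean) —
    proportional noise, the regime that motivates 1/C weighting.
    """
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if any(c < 0 for c in levels):
        raise ParameterError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for conc in levels:
        mean = true_slope * conc + true_intercept
        sd = cv * abs(mean)
        ratios = rng.normal(mean, sd, size=replicates) if sd > 0 \
            else np.full(replicates, mean)
        out.append(CalLevel(nominal_conc=float(conc),
                            replicate_ratios=ratios))
    return out


def simulate_counts(
    n_genes: int,
    n_cells: int,
    target_fractions: dict[str, float],
    mean_count: float = 2.0,
    background_fraction: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """Simulate a sparse genes x cells count matrix.

    Every gene named in ``target_fractions`` is expressed (count > 0) in
    each cell independently with its stated probability; remaining filler
    genes use ``background_fraction``. Positive counts are 1 + Poisson
    draws, so the expression fraction is exactly the gating probability.
    """
    if n_genes < len(target_fractions):
        raise ParameterError("n_genes smaller than the number of target genes")
    for gene, p in target_fractions.items():
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"probability for {gene!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = list(target_fractions) + [
        f"Filler{i:04d}" for i in range(n_genes - len(target_fractions))
    ]
    probs = list(target_fractions.values()) + [background_fraction] * (
        n_genes - len(target_fractions)
    )
    rows, cols, vals = [], [], []
    extra = max(mean_count - 1.0, 0.0)
    for gi, p in enumerate(probs):
        mask = rng.random(n_cells) < p
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        counts = 1 + rng.poisson(extra, size=len(idx))
        rows.append(np.full(len(idx), gi))
        cols.append(idx)
        vals.append(counts)
    if rows:
        mat = sparse.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_genes, n_cells), dtype=np.int64,
        ).tocsr()
    else:
        mat = sparse.csr_matrix((n_genes, n_cells), dtype=np.int64)
    barcodes = [f"CELL{i:06d}" for i in range(n_cells)]
    return CountMatrix(counts=mat, gene_ids=gene_ids, cell_ids=barcodes)
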