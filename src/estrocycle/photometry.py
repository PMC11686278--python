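"""Two-channel fiber-photometry preprocessing.

The analysis trace used everywhere downstream is produced by a fixed
pipeline: denoise both channels at the acquisition rate (median filter then
zero-phase lowpass), drop the assay-specific startup window, block-average
downsample, regress the 405 nm isosbestic channel out of the 465 nm GCaMP
channel, and z-score the residual over the whole analyzed trace.

The isosbestic channel is insensitive to calcium, so a linear fit of it to
the signal channel estimates the shared motion/bleaching component; the
correction is the ordinary-least-squares residual, which is exactly mean
zero and uncorrelated with the fitted regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

from .errors import DataError, DegenerateDataError, ParameterError

#: seconds excluded from the start of every recording, per assay, to remove
#: transfer/bottle-change artifacts
START_EXCLUSION_S = {"EPM": 150.0, "OF": 400.0, "DID": 1000.0}

NOMINAL_FS = 1017.25  # Hz, acquisition rate of the photometry system


@dataclass
class EpochInterval:
    """Labeled half-open access interval [start_s, end_s)."""

    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class RawSession:
    """Aligned two-channel photometry recording with behavioral sidecars.

    ``f465`` carries the calcium-dependent GCaMP signal, ``f405`` the
    calcium-independent isosbestic control; both are sampled on the same
    clock at ``fs``.
    """

    time_s: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs: float = NOMINAL_FS
    assay: str = "DID"
    licks: np.ndarray = field(default_factory=lambda: np.empty(0))
    epoch_schedule: list[EpochInterval] = field(default_factory=list)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        self.licks = np.asarray(self.licks, dtype=float)
        if not (len(self.time_s) == len(self.f465) == len(self.f405)):
            raise DataError("time and channel arrays must have equal length")
        if self.assay not in START_EXCLUSION_S:
            raise ParameterError(
                f"assay must be one of {sorted(START_EXCLUSION_S)}, got {self.assay!r}"
            )

    @property
    def duration_s(self) -> float:
        return len(self.time_s) / self.fs


@dataclass
class MotionFit:
    """OLS fit of the isosbestic channel to the signal channel."""

    slope: float
    intercept: float
    r: float


@dataclass
class ProcessedTrace:
    """Motion-corrected, whole-trace z-scored photometry trace."""

    time_s: np.ndarray
    z: np.ndarray
    fs_eff: float
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.z = np.asarray(self.z, dtype=float)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    median_window
        samples, odd; default 5 removes single-sample electrical artifacts.
    lowpass_hz
        corner of the 2nd-order zero-phase Butterworth; 3 Hz comfortably
        covers GCaMP6s kinetics at a tenth of the effective Nyquist.
    downsample_factor
        block-mean length; 100 brings 1017.25 Hz to ~10.17 Hz.
    """

    median_window: int = 5
    lowpass_hz: float = 3.0
    downsample_factor: int = 100
    start_exclusion_s: float | None = None  # None -> assay default
    motion_correct: bool = True  # False: skip the isosbestic regression


def denoise(channel: np.ndarray, fs: float, median_window: int = 5,
            lowpass_hz: float = 3.0) -> np.ndarray:
    """Median-filter then zero-phase lowpass a raw channel.

    The median filter removes isolated electrical artifacts without ringing;
    the forward-backward Butterworth removes high-frequency sensor noise
    with zero phase delay so event times are preserved.
    """
    channel = np.asarray(channel, dtype=float)
    if median_window < 3 or median_window % 2 == 0:
        raise ParameterError("median_window must be odd and >= 3")
    if not 0 < lowpass_hz < fs / 2:
        raise ParameterError("lowpass cutoff must lie in (0, fs/2)")
    out = signal.medfilt(channel, kernel_size=median_window)
    sos = signal.butter(2, lowpass_hz, btype="low", fs=fs, output="sos")
    padlen = min(len(out) - 1, 3 * (2 * 2 + 1) * 10)
    return signal.sosfiltfilt(sos, out, padlen=padlen)


def trim_start(session: RawSession, exclusion_s: float | None = None) -> RawSession:
    """Drop the assay-specific startup window and clip the epoch schedule.

    Samples with ``time_s < exclusion`` are removed; epochs are clipped to
    the remaining support and emptied epochs dropped.
    """
    if exclusion_s is None:
        exclusion_s = START_EXCLUSION_S[session.assay]
    if exclusion_s < 0:
        raise ParameterError("exclusion must be >= 0")
    if session.duration_s <= exclusion_s:
        raise DataError(
            f"session of {session.duration_s:.1f}s shorter than "
            f"{exclusion_s:.1f}s exclusion"
        )
    keep = session.time_s >= exclusion_s
    schedule = []
    for ep in session.epoch_schedule:
        start = max(ep.start_s, exclusion_s)
        if start < ep.end_s:
            schedule.append(EpochInterval(ep.label, start, ep.end_s))
    return replace(
        session,
        time_s=session.time_s[keep],
        f465=session.f465[keep],
        f405=session.f405[keep],
        epoch_schedule=schedule,
    )


def downsample_mean(channel: np.ndarray, factor: int = 100) -> np.ndarray:
    """Non-overlapping block means; the trailing partial block is dropped."""
    if factor < 1 or int(factor) != factor:
        raise ParameterError("downsample factor must be an integer >= 1")
    channel = np.asarray(channel, dtype=float)
    factor = int(factor)
    if factor == 1:
        return channel.copy()
    n_blocks = len(channel) // factor
    return channel[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)


def motion_correct(f465: np.ndarray, f405: np.ndarray) -> tuple[np.ndarray, MotionFit]:
    """Subtract the best linear fit of the isosbestic channel from the signal.

    Returns the OLS residual ``f465 - (slope*f405 + intercept)`` together
    with the fit. The residual is mean zero and uncorrelated with the fitted
    component by construction.
    """
    f465 = np.asarray(f465, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if len(f465) != len(f405):
        raise DataError("channels must have equal length")
    if len(f465) < 3:
        raise DataError("need at least 3 samples to fit motion")
    if np.ptp(f405) == 0:
        raise DegenerateDataError("isosbestic channel is constant; cannot fit")
    res = stats.linregress(f405, f465)
    corrected = f465 - (res.slope * f405 + res.intercept)
    return corrected, MotionFit(slope=float(res.slope),
                                intercept=float(res.intercept),
                                r=float(res.rvalue))


def zscore_trace(channel: np.ndarray) -> np.ndarray:
    """Whole-trace z-score with sample standard deviation (ddof=1)."""
    channel = np.asarray(channel, dtype=float)
    if len(channel) < 2:
        raise DataError("need at least 2 samples to z-score")
    sd = channel.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("trace has zero variance")
    return (channel - channel.mean()) / sd


def preprocess(session: RawSession,
               config: PreprocessConfig | None = None) -> ProcessedTrace:
    """Run the full preprocessing pipeline on a session.

    Order is fixed: denoise both channels at the acquisition rate, trim the
    startup window, block-mean downsample, motion-correct on the downsampled
    channels, z-score. Every step and its parameters are recorded in
    ``provenance``.
    """
    cfg = config or PreprocessConfig()
    prov: list[dict] = []

    f465 = denoise(session.f465, session.fs, cfg.median_window, cfg.lowpass_hz)
    f405 = denoise(session.f405, session.fs, cfg.median_window, cfg.lowpass_hz)
    prov.append({"step": "denoise", "median_window": cfg.median_window,
                 "lowpass_hz": cfg.lowpass_hz})

    trimmed = replace(session, f465=f465, f405=f405)
    exclusion = (START_EXCLUSION_S[session.assay]
                 if cfg.start_exclusion_s is None else cfg.start_exclusion_s)
    if exclusion > 0:
        trimmed = trim_start(trimmed, exclusion)
    prov.append({"step": "trim_start", "exclusion_s": exclusion})

    f465d = downsample_mean(trimmed.f465, cfg.downsample_factor)
    f405d = downsample_mean(trimmed.f405, cfg.downsample_factor)
    timed = downsample_mean(trimmed.time_s, cfg.downsample_factor)
    fs_eff = session.fs / cfg.downsample_factor
    prov.append({"step": "downsample_mean", "factor": cfg.downsample_factor,
                 "fs_eff": fs_eff})

    if cfg.motion_correct:
        corrected, fit = motion_correct(f465d, f405d)
        prov.append({"step": "motion_correct", "slope": fit.slope,
                     "intercept": fit.intercept, "r": fit.r})
    else:
        corrected = f465d
        prov.append({"step": "motion_correct", "skipped": True})

    z = zscore_trace(corrected)
    prov.append({"step": "zscore", "ddof": 1})

    return ProcessedTrace(time_s=timed, z=z, fs_eff=fs_eff, provenance=prov)
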