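"""LC-MS/MS quantification arithmetic for 17β-estradiol.

The calibration curve is a weighted (1/C) linear regression of the
analyte/internal-standard peak-area ratio on nominal concentration;
unknowns are back-calculated by inverting the line. The lower limit of
quantification (LLOQ) is the smallest calibration level whose
back-calculated replicates have mean accuracy within 80-120% (inclusive)
and CV below 20% (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import DataError, DegenerateDataError, ParameterError


@dataclass
class CalLevel:
    """One calibration standard: nominal concentration + replicate ratios."""

    nominal_conc: float
    replicate_ratios: np.ndarray

    def __post_init__(self):
        self.replicate_ratios = np.atleast_1d(
            np.asarray(self.replicate_ratios, dtype=float)
        )
        if self.nominal_conc < 0:
            raise DataError("nominal concentration must be >= 0")
        if not np.all(np.isfinite(self.replicate_ratios)):
            raise DataError("replicate ratios must be finite")


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    n_points: int
    weights: np.ndarray


@dataclass
class LevelEvaluation:
    nominal_conc: float
    accuracy_pct: float
    cv_pct: float
    passes: bool


@dataclass
class LloqResult:
    lloq: float | None
    defined: bool
    per_level: list[LevelEvaluation]


def serial_dilution_design(high_conc: float = 4.0,
                           n_standards: int = 14) -> list[float]:
    """Two-fold serial dilution series from the high standard, plus a blank.

    Defaults give 13 nonzero levels from 4 ng/ml down to 4/2**12 ng/ml
    (~0.98 pg/ml) and a blank, 14 standards in total.
    """
    if n_standards < 2:
        raise ParameterError("need at least 2 standards (one level + blank)")
    if high_conc <= 0:
        raise ParameterError("high standard concentration must be > 0")
    levels = [high_conc / 2**i for i in range(n_standards - 1)]
    return levels + [0.0]


def fit_calibration(levels: list[CalLevel],
                    per_level_mean: bool = False) -> CalibrationFit:
    """Weighted least-squares calibration line with 1/C weights.

    Each replicate at each nonzero level contributes one point with weight
    1/C (the blank is excluded: its weight is undefined). With
    ``per_level_mean=True`` the fit uses level means instead of replicates.
    """
    concs, ratios = [], []
    for lev in levels:
        if lev.nominal_conc == 0:
            continue
        if per_level_mean:
            concs.append(lev.nominal_conc)
            ratios.append(float(np.mean(lev.replicate_ratios)))
        else:
            concs.extend([lev.nominal_conc] * len(lev.replicate_ratios))
            ratios.extend(lev.replicate_ratios.tolist())
    concs = np.asarray(concs, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if len(np.unique(concs)) < 2:
        raise DataError("need >= 2 distinct nonzero concentrations to fit")
    weights = 1.0 / concs
    model = sm.WLS(ratios, sm.add_constant(concs), weights=weights)
    res = model.fit()
    return CalibrationFit(slope=float(res.params[1]),
                          intercept=float(res.params[0]),
                          n_points=len(concs), weights=weights)


def back_calculate(ratio: float | np.ndarray,
                   fit: CalibrationFit) -> np.ndarray:
    """Invert the calibration line: C = (ratio - intercept) / slope.

    Values below the blank come out negative and are reported as-is.
    """
    if fit.slope == 0:
        raise DegenerateDataError("zero slope; calibration is uninvertible")
    return (np.asarray(ratio, dtype=float) - fit.intercept) / fit.slope


def evaluate_level(level: CalLevel, fit: CalibrationFit) -> LevelEvaluation:
    """Accuracy and CV of back-calculated replicates at one level."""
    back = back_calculate(level.replicate_ratios, fit)
    mean_back = float(np.mean(back))
    accuracy = mean_back / level.nominal_conc * 100.0
    cv = float(np.std(back, ddof=1) / abs(mean_back) * 100.0) \
        if mean_back != 0 else float("inf")
    passes = (80.0 <= accuracy <= 120.0) and (cv < 20.0)
    return LevelEvaluation(nominal_conc=level.nominal_conc,
                           accuracy_pct=accuracy, cv_pct=cv, passes=passes)


def determine_lloq(levels: list[CalLevel], fit: CalibrationFit) -> LloqResult:
    """Smallest nonzero level with accuracy in [80, 120] and CV < 20%.

    Levels with a single replicate cannot yield a CV and are skipped with
    a warning; if no level passes, the result is flagged undefined.
    """
    evals = []
    for lev in sorted(levels, key=lambda l: l.nominal_conc):
        if lev.nominal_conc == 0:
            continue
        if len(lev.replicate_ratios) < 2:
            warnings.warn(
                f"level {lev.nominal_conc}: single replicate, skipped "
                "(CV undefined)", stacklevel=2)
            continue
        evals.append(evaluate_level(lev, fit))
    passing = [e.nominal_conc for e in evals if e.passes]
    if passing:
        return LloqResult(lloq=min(passing), defined=True, per_level=evals)
    return LloqResult(lloq=None, defined=False, per_level=evals)
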