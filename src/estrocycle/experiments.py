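"""End-to-end simulation experiments exercising each pipeline stage.

Each function generates its inputs from the synthetic module under a
caller-supplied seed, runs the corresponding analysis stage, and returns
the measured quantities. The ``analysis/`` drivers and the acceptance
script are thin wrappers around these.

Problem sizes are chosen to keep a full run in the low minutes on one
core; see docs/methods.md for the session lengths and rates used and why.
"""

from __future__ import annotations

import numpy as np

from . import bouts, calibration, ephys, expression, stats, transients
from .photometry import (EpochInterval, PreprocessConfig, downsample_mean,
                         motion_correct, preprocess)
from .synthetic import (PhotometrySimParams, simulate_calibration,
                        simulate_counts, simulate_licks, simulate_photometry,
                        simulate_psc_stream)

PSC_WINDOWS = {"baseline": (0.0, 600.0), "wash": (600.0, 1200.0),
               "washout": (1200.0, 1800.0)}


def _spawn(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------- photometry

def motion_correction_experiment(seed: int = 0, n_sessions: int = 100,
                                 duration_s: float = 120.0,
                                 fs: float = 1017.25) -> dict:
    """Preprocessing contract under motion twice the sensor noise.

    Returns the z mean/sd worst-case deviations and the average fractional
    drop in ground-truth-motion-explained variance after isosbestic
    correction.
    """
    drops, z_mean_err, z_sd_err = [], 0.0, 0.0
    for s in _spawn(seed, n_sessions):
        p = PhotometrySimParams(duration_s=duration_s, fs=fs, seed=s,
                                transient_rate=6.0, motion_amp=0.6,
                                noise_sd=0.3)
        session, gt = simulate_photometry(p)
        tr = preprocess(session, PreprocessConfig(start_exclusion_s=0))
        z_mean_err = max(z_mean_err, abs(float(tr.z.mean())))
        z_sd_err = max(z_sd_err, abs(float(tr.z.std(ddof=1)) - 1.0))
        f465 = downsample_mean(session.f465, 100)
        f405 = downsample_mean(session.f405, 100)
        motion = downsample_mean(gt.motion_trace, 100)
        corrected, _ = motion_correct(f465, f405)

        def explained(x):
            return np.corrcoef(x, motion)[0, 1] ** 2 * np.var(x)

        drops.append(1.0 - explained(corrected) / explained(f465))
    return {"n_sessions": n_sessions,
            "max_abs_z_mean": z_mean_err,
            "max_abs_z_sd_minus_1": z_sd_err,
            "mean_variance_drop": float(np.mean(drops)),
            "min_variance_drop": float(np.min(drops))}


# --------------------------------------------------------------------- bouts

def brute_force_bouts(licks, max_ili=1.0, min_licks=2, min_duration=0.5):
    """Exhaustive bout oracle: every maximal contiguous subset obeying the
    inter-lick rule, filtered by the count and duration minima."""
    licks = list(licks)
    n = len(licks)
    out = []
    for i in range(n):
        for j in range(i, n):
            sub = licks[i:j + 1]
            if any(b - a > max_ili for a, b in zip(sub, sub[1:])):
                continue
            if i > 0 and licks[i] - licks[i - 1] <= max_ili:
                continue
            if j < n - 1 and licks[j + 1] - licks[j] <= max_ili:
                continue
            if len(sub) >= min_licks and sub[-1] - sub[0] >= min_duration:
                out.append((sub[0], sub[-1], len(sub)))
    return out


def bout_oracle_experiment(seed: int = 0, n_trials: int = 1000) -> dict:
    """Greedy clustering vs the exhaustive oracle on random lick trains."""
    agree = 0
    for s in _spawn(seed, n_trials):
        rng = np.random.default_rng(s)
        n = int(rng.integers(0, 13))
        licks = np.sort(rng.uniform(0, 15, size=n))
        if len(licks) > 1:
            licks = licks[np.concatenate([[True], np.diff(licks) > 1e-9])]
        got = [(b.onset, b.offset, b.n_licks)
               for b in bouts.detect_bouts(licks)]
        agree += got == brute_force_bouts(licks)
    return {"n_trials": n_trials, "agreement": agree / n_trials}


def bout_round_trip_experiment(seed: int = 0, n_trials: int = 50) -> dict:
    """Scheduled bouts recovered exactly by the detector."""
    exact = 0
    for s in _spawn(seed, n_trials):
        rng = np.random.default_rng(s)
        onsets = np.cumsum(rng.uniform(15, 30, size=6))
        schedule = [(float(o), int(rng.integers(2, 12))) for o in onsets]
        licks = simulate_licks(schedule, seed=s)
        exact += len(bouts.detect_bouts(licks)) == len(schedule)
    return {"n_trials": n_trials, "exact_recovery": exact / n_trials}


# ---------------------------------------------------------------- transients

def transient_recovery_experiment(seed: int = 0, n_sessions: int = 50,
                                  duration_s: float = 600.0,
                                  fs: float = 200.0) -> dict:
    """Detector sensitivity/FDR when amplitudes are >= 5x the noise sd."""
    sens, fdr = [], []
    for s in _spawn(seed, n_sessions):
        p = PhotometrySimParams(duration_s=duration_s, fs=fs, seed=s,
                                transient_rate=6.0, transient_amp_mean=3.0,
                                transient_amp_sd=0.5, noise_sd=0.3,
                                motion_amp=0.3)
        session, gt = simulate_photometry(p)
        tr = preprocess(session, PreprocessConfig(downsample_factor=20,
                                                  start_exclusion_s=0))
        ev = transients.detect_transients(tr)
        m = transients.match_events(ev, gt.transient_times, tol_s=0.5,
                                    resolvable_gap_s=1.0)
        sens.append(m["sensitivity"])
        fdr.append(m["fdr"])
    return {"n_sessions": n_sessions,
            "sensitivity": float(np.mean(sens)),
            "fdr": float(np.mean(fdr))}


def dissociation_experiment(seed: int = 0, rate_mult: float = 2.0,
                            amp_shift: float = 2.0) -> dict:
    """Rate vs amplitude dissociation in the W1-normalized distributions.

    Simulates a reference (W1-like) event population, one population with
    the transient rate multiplied, and one with the mean amplitude shifted,
    then measures AUC and peak of each W1-normalized distribution.
    """
    s1, s2, s3 = _spawn(seed, 3)
    ep = transients.EPOCH_LEN_S
    epoch = EpochInterval("E", 0.0, ep)

    def population(rate_per_min, amp_mean, s):
        rng = np.random.default_rng(s)
        n = rng.poisson(rate_per_min * ep / 60.0)
        return [transients.TransientEvent(float(t), float(a))
                for t, a in zip(rng.uniform(0, ep, n),
                                np.abs(rng.normal(amp_mean, 0.4, n)))]

    ref = population(10.0, 3.0, s1)
    more = population(10.0 * rate_mult, 3.0, s2)
    bigger = population(10.0, 3.0 + amp_shift, s3)

    d_ref = transients.amplitude_distribution(ref, epoch, ref, epoch)
    d_more = transients.amplitude_distribution(more, epoch, ref, epoch)
    d_big = transients.amplitude_distribution(bigger, epoch, ref, epoch)
    sm_ref = transients.summarize_distribution(d_ref)
    sm_more = transients.summarize_distribution(d_more)
    sm_big = transients.summarize_distribution(d_big)
    return {"ref_auc": sm_ref.auc, "rate_auc": sm_more.auc,
            "auc_ratio": sm_more.auc / sm_ref.auc,
            "rate_peak_shift": sm_more.peak_amplitude - sm_ref.peak_amplitude,
            "amp_peak_shift": sm_big.peak_amplitude - sm_ref.peak_amplitude,
            "bin_width": float(d_ref.bin_edges[1] - d_ref.bin_edges[0])}


# --------------------------------------------------------------------- ephys

def wash_response_experiment(seed: int = 0, n_cells: int = 100,
                             wash_multiplier: float = 3.55,
                             baseline_rate: float = 2.0) -> dict:
    """Peak % baseline during wash-on, estimated over simulated cells.

    The estimator uses one wash-long bin (the unbiased long-window limit);
    the Monte-Carlo mean and standard error over cells are reported.
    """
    peaks = []
    wash_len = PSC_WINDOWS["wash"][1] - PSC_WINDOWS["wash"][0]
    for s in _spawn(seed, n_cells):
        stream = simulate_psc_stream(baseline_rate, 20.0, wash_multiplier,
                                     PSC_WINDOWS, seed=s)
        tc = ephys.percent_baseline_timecourse(stream, "frequency",
                                               bin_s=wash_len / 2)
        peaks.append(float(np.mean(tc.pct_baseline[tc.wash_mask])))
    peaks = np.asarray(peaks)
    return {"n_cells": n_cells,
            "mean_peak_pct": float(peaks.mean()),
            "mc_se": float(peaks.std(ddof=1) / np.sqrt(n_cells))}


def responder_oracle_experiment(seed: int = 0, n_trials: int = 10_000) -> dict:
    """Two-rule classifier vs an inline brute-force re-evaluation."""
    agree = 0
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    for _ in range(n_trials):
        wash = rng.uniform(0.0, 300.0, size=int(rng.integers(1, 12)))
        pct = np.concatenate([[100.0, 100.0], wash])
        mask = np.zeros(len(pct), dtype=bool)
        mask[2:] = True
        tc = ephys.Timecourse(bin_edges=np.arange(len(pct) + 1) * 60.0,
                              pct_baseline=pct, metric="frequency",
                              wash_mask=mask, baseline_mean=1.0)
        call = ephys.classify_responder(tc)
        mean_d = wash.mean() - 100.0
        deltas = wash - 100.0
        big = deltas[np.argmax(np.abs(deltas))]
        fires_mean, fires_min = abs(mean_d) >= 15.0, abs(big) >= 50.0
        if not (fires_mean or fires_min):
            want = "no_change"
        elif fires_mean and (not fires_min or abs(mean_d) >= abs(big)):
            want = "increase" if mean_d > 0 else "decrease"
        else:
            want = "increase" if big > 0 else "decrease"
        agree += call.category == want
    return {"n_trials": n_trials, "agreement": agree / n_trials}


def antagonist_cohort_experiment(seed: int = 0,
                                 suppressed_multiplier: float = 0.515,
                                 n_suppressed: int = 5,
                                 n_unaffected: int = 2) -> dict:
    """ER-antagonist-like cohort: a majority of cells with wash-on
    frequency suppressed to ~51.5% of baseline, the rest unchanged.

    Classifies every simulated cell and reports the decrease fraction and
    the mean wash-on % of baseline among decreasing cells.
    """
    n_cells = n_suppressed + n_unaffected
    seeds = _spawn(seed, n_cells)
    mults = [suppressed_multiplier] * n_suppressed + [1.0] * n_unaffected
    calls, wash_pct = [], []
    for s, mult in zip(seeds, mults):
        stream = simulate_psc_stream(2.0, 20.0, mult, PSC_WINDOWS, seed=s)
        tc = ephys.percent_baseline_timecourse(stream, "frequency",
                                               bin_s=60.0)
        call = ephys.classify_responder(tc)
        calls.append(call)
        if call.category == "decrease":
            wash_pct.append(float(np.mean(tc.pct_baseline[tc.wash_mask])))
    fracs = ephys.cohort_response_summary(calls)
    return {"n_cells": n_cells,
            "decrease_fraction": fracs["decrease"],
            "mean_decrease_pct_baseline":
                float(np.mean(wash_pct)) if wash_pct else float("nan")}


# --------------------------------------------------------------- calibration

def calibration_experiment(seed: int = 0, n_seeds: int = 200,
                           true_slope: float = 0.5, cv: float = 0.08) -> dict:
    """Weighted-fit recovery, weighted-vs-unweighted low-end RMSE, and the
    LLOQ of the default two-fold dilution design."""
    design = calibration.serial_dilution_design()
    nonzero = [c for c in design if c > 0]
    lows = [c for c in nonzero if c <= 0.01]

    exact = simulate_calibration(true_slope, 0.0, nonzero, replicates=3,
                                 cv=0.0, seed=0)
    fit0 = calibration.fit_calibration(exact)
    slope_err = abs(fit0.slope - true_slope) / true_slope

    err_w, err_u, lloqs = [], [], []
    for s in _spawn(seed, n_seeds):
        levels = simulate_calibration(true_slope, 0.0, nonzero,
                                      replicates=3, cv=cv, seed=s)
        fit_w = calibration.fit_calibration(levels)
        concs = np.concatenate([[l.nominal_conc] * 3 for l in levels])
        ratios = np.concatenate([l.replicate_ratios for l in levels])
        s_u, i_u = np.polyfit(concs, ratios, 1)
        fit_u = calibration.CalibrationFit(float(s_u), float(i_u),
                                           len(concs), np.ones(len(concs)))
        for c in lows:
            ratio = true_slope * c
            err_w.append(float(calibration.back_calculate(ratio, fit_w) - c) ** 2)
            err_u.append(float(calibration.back_calculate(ratio, fit_u) - c) ** 2)
        res = calibration.determine_lloq(levels, fit_w)
        if res.defined:
            lloqs.append(res.lloq)
    return {"n_seeds": n_seeds,
            "noise_free_slope_rel_err": slope_err,
            "rmse_weighted": float(np.sqrt(np.mean(err_w))),
            "rmse_unweighted": float(np.sqrt(np.mean(err_u))),
            "median_lloq_ng_ml": float(np.median(lloqs)),
            "median_lloq_pg_ml": float(np.median(lloqs)) * 1000.0,
            "lowest_standard_pg_ml": min(nonzero) * 1000.0}


# ---------------------------------------------------------------- expression

#: expression probabilities used for the synthetic BNST-like matrix; the
#: marginals mirror the receptor prevalences the pipeline is meant to
#: measure, co-expression is independent by construction
BNST_FRACTIONS = {"Esr1": 0.293, "Esr2": 0.067, "Gper1": 0.003,
                  "Crh": 0.10, "Slc17a6": 0.35}
BNST_N_CELLS = 38_806


def expression_experiment(seed: int = 0, n_cells: int = BNST_N_CELLS,
                          n_genes: int = 50) -> dict:
    """Expression fractions on a simulated BNST-scale count matrix."""
    cm = simulate_counts(n_genes, n_cells, BNST_FRACTIONS,
                         seed=_spawn(seed, 1)[0])
    out = {"n_cells": n_cells}
    for gene in ("Esr1", "Esr2", "Gper1"):
        out[f"{gene.lower()}_pct"] = \
            expression.expression_fraction(cm, gene).fraction * 100.0
    out["esr1_in_crh_pct"] = expression.coexpression_fraction(
        cm, "Esr1", within="Crh").fraction * 100.0
    out["esr1_esr2_both_pct"] = expression.coexpression_fraction(
        cm, "Esr1", "Esr2").fraction * 100.0
    return out


# --------------------------------------------------------------------- stats

def stats_experiment(seed: int = 0, n_reps: int = 10_000) -> dict:
    """Welch type-I error under an unequal-variance null, plus the
    closed-form Holm-Sidak family check."""
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(0.0, 1.0, size=10)
        y = rng.normal(0.0, 3.0, size=15)
        rejections += stats.t_test(x, y).p_raw < 0.05
    adj = stats.holm_sidak([0.05, 0.05, 0.05])
    return {"n_reps": n_reps,
            "type_i_error": rejections / n_reps,
            "holm_sidak_triplet": float(adj[0])}
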