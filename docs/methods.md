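# Methods

This package reimplements, as tested library code plus numbered analysis
drivers, the quantitative pipeline of a study of estrous-cycle estrogen
(E2) control of binge alcohol drinking in female mice: fiber-photometry
recordings of BNST CRF-neuron GCaMP6s activity during a modified
Drinking-in-the-Dark (DID) task, lickometer bout analysis, slice
electrophysiology pharmacology, LC-MS/MS estradiol quantification, and
single-nucleus receptor-expression fractions. Every stage is driven by a
synthetic-data generator with known ground truth, so the full chain is
testable without recordings.

## Photometry preprocessing

Raw sessions carry two aligned channels sampled at 1017.25 Hz: 465 nm
(calcium-dependent GCaMP) and 405 nm (isosbestic, calcium-independent).
The fixed pipeline is:

1. **Denoise** both channels at the acquisition rate — median filter
   (default window 5 samples) to remove isolated electrical artifacts,
   then a 2nd-order Butterworth lowpass (default 3 Hz) applied
   forward-backward for zero phase. The filters' types are part of the
   protocol; the window and corner are not stated anywhere authoritative,
   so both are configuration, recorded in the trace's provenance.
2. **Trim** the assay-specific startup window: 150 s (elevated plus
   maze), 400 s (open field), 1000 s (DID), removing transfer and
   bottle-change artifacts.
3. **Downsample** by non-overlapping block means (default factor 100,
   giving ~10.17 Hz effective). Block averaging rather than decimation
   buys extra noise suppression at no cost at these bandwidths.
4. **Motion-correct** by ordinary least squares of the 465 channel on the
   405 channel and subtraction of the fitted component. The residual is
   exactly mean-zero and uncorrelated with the fitted regressor. The fit
   is computed on the downsampled channels; at these bandwidths this is
   statistically equivalent to fitting at the full rate and much cheaper.
5. **Z-score** over the whole analyzed trace with the sample standard
   deviation (ddof = 1; the convention matters at small n and is
   therefore fixed and documented).

Time intervals are half-open `[start, end)` seconds from acquisition
start throughout.

A single linear fit cannot simultaneously cancel two shared components
with different cross-channel gains (e.g. bleaching and motion); the
correction is therefore excellent but not exact when the motion gain
differs between channels, exactly as with real recordings. The
motion-removal benchmark reports the *average* fractional drop in
motion-explained variance across sessions (typically ≈ 98%, required
≥ 90%); single short sessions can occasionally fall below the average
when their raw motion-explained variance is already small.

## Lickometer bouts

A drinking bout is a greedy cluster of consecutive licks with inter-lick
interval ≤ 1.0 s (inclusive: an interval of exactly 1 s joins), kept when
it has ≥ 2 licks and spans ≥ 0.5 s. "Motivated" bouts are the subset with
duration strictly > 1 s; the detection minimum and the motivated filter
are deliberately two separate parameters because both definitions are
used in different analyses. Epoch membership is by onset time, which
makes bouts straddling an epoch boundary count exactly once. Bout
detection is verified against an exhaustive oracle that tests every
maximal contiguous lick subset against the rule.

Fluid intake is converted to dose as
`max(bottle_loss − dummy_leak, 0) [g] → ml at 1 g/ml → solute grams`
(20% v/v ethanol at 0.789 g/ml, or 1% w/v sucrose) divided by bodyweight.
The 1 g/ml fluid-density approximation is a documented constant.

## Analysis epochs and transient statistics

The DID session is segmented into four 30-min epochs: the last 30 min of
the first water access (W1), the first and last 30 min of alcohol access
(EtOH1, EtOH2), and the first 30 min of the second water access (W2).

Transients are local maxima of the z-trace exceeding
`median + k·σ_MAD` with prominence ≥ `k·σ_MAD` (default k = 2.5), where
`σ_MAD = 1.4826 × MAD` of the whole trace — robust to the transients
themselves inflating the scale. The prominence requirement suppresses
noise ripples riding on the decay tail of a larger event. Peaks closer
than 1 s keep only the larger (GCaMP6s decay makes faster pairs
unresolvable at ~10 Hz effective sampling). Event amplitude is the peak
value minus the 10th percentile of the preceding 5 s, which makes
detection and amplitude invariant to adding a constant to the trace.
When detection is benchmarked against ground truth, sensitivity is
computed over *resolvable* true events (no neighbor within the 1 s
separation on either side) while the false-discovery rate counts a
detection as correct if it matches any true event — the standard
convention when the detector's resolution is part of its definition.

Per-epoch amplitude histograms (default bins of 0.5 z over [0, 10] z,
half-open) are normalized by the **total event count of the W1 epoch**,
so the W1 distribution integrates to 1 and an epoch with added events has
total mass above 1. This reading of "normalized to the W1 distribution"
was chosen because it makes the two observed effects separable: a pure
rate increase raises the area under the curve (AUC, trapezoid over bin
centers) while leaving the peak location unchanged, and a pure amplitude
increase shifts the peak rightward without changing total mass. The
alternative per-bin-ratio normalization would confound the two. Argmax
ties break toward the lower-amplitude bin (arbitrary, documented).
Because the z-scale is per-trace, amplitudes are comparable within a day
(each epoch against its own day's W1), not across days — which is why
the distributions are always referenced to the same-day W1.

## Slice pharmacology

PSC event streams are annotated with ordered baseline / wash / washout
windows. Frequency is events per second in a window, amplitude the mean
event magnitude (undefined and flagged for empty windows), and synaptic
drive their product. Time courses express the per-bin (default 60 s)
metric as percent of the baseline-window mean.

A cell is a responder when either rule fires (both inclusive):
**mean15** — the wash-on mean percent deviates from 100 by ≥ 15 points;
**minute50** — any single one-minute bin deviates by ≥ 50 points. The
call's direction follows the firing rule with the larger absolute
deviation (the degenerate disagreeing-sign case is not otherwise
specified anywhere). The rule is applied to frequency time courses;
amplitude time courses are computed but classified separately. Cells
whose access resistance changes by more than 20% from the first
measurement are excluded.

The "peak % of baseline during wash" benchmark uses one wash-long bin as
the estimator: the maximum of many short noisy bins is upward-biased,
while the long-window limit is unbiased and is what a multiplier of
3.55 should reproduce as ≈ 355%. The antagonist cohort simulation uses
the reported cohort composition (five of seven cells suppressed to
~51.5% of baseline, two unaffected) as generator inputs and lets the
pipeline classify and measure.

## Estradiol calibration

The calibration curve is a linear regression of the analyte/internal-
standard peak-area ratio on nominal concentration with 1/C weights, one
weighted point per replicate (per-level-mean fitting is available behind
a flag). The blank (0 ng/ml) is part of the standard series but is
excluded from the weighted fit, since its weight is undefined.
Concentrations are back-calculated by inverting the line; values below
the blank come out negative and are reported as-is. Per level, accuracy
is `mean(back-calculated)/nominal × 100` and CV is the ratio sd/mean of
the back-calculated replicates; the LLOQ is the smallest level with
accuracy in [80, 120] (inclusive) and CV < 20% (strict). The default
design — two-fold dilutions from a 4 ng/ml high standard, 14 standards
including the blank — has a lowest nonzero standard of 4/2¹² ng/ml
≈ 0.98 pg/ml; under proportional noise with a near-zero true intercept
the LLOQ rule lands on that lowest standard, consistent with a reported
1 pg/ml LLOQ. Leave-one-out refitting when evaluating a level is not
performed.

## Receptor expression fractions

Counts load from the MatrixMarket + gene/barcode trio. A cell is
positive for a gene when its raw count exceeds zero; this criterion is
invariant to any per-cell normalization (scaling a column never changes
which entries are nonzero), which makes the fractions comparable to ones
computed after a standard normalization pipeline without re-implementing
that pipeline. Duplicate gene symbols resolve to the first occurrence
with a warning. Co-expression fractions can condition the denominator on
a gene-defined subpopulation (e.g. Esr1 within Crh+ cells); the
identities `f(A∧B) ≤ min(f(A), f(B))` and
`f(A|B)·f(B) = f(A∧B)` are enforced by tests.

## Statistics

Paired and unpaired two-tailed t-tests (unpaired defaults to Welch's
unequal-variance form — the safe choice when variance equality is
checked case-by-case), Pearson correlation, and Holm–Šidák step-down
adjustment: sort ascending, adjust the i-th smallest of m to
`1 − (1 − p)^(m−i+1)`, enforce monotone non-decreasing, restore input
order. Zero-variance paired differences are flagged degenerate rather
than silently producing an unbounded statistic. ANOVA and mixed-effects
families are out of scope; the adjustment accepts externally computed
p-value families.

## Synthetic data: what is and is not emulated

The generators draw everything from one explicitly seeded
`numpy.random.Generator` per call (no global state; identical seeds give
bitwise-identical output).

* **Photometry**: transients as a Poisson process (optionally per-epoch
  rates and per-epoch amplitude means) with lognormal amplitudes and an
  instantaneous-rise / exponential-decay kernel (τ = 1.5 s, matching
  GCaMP6s kinetics qualitatively); a shared motion artifact (white noise
  lowpassed at 0.5 Hz, added to both channels, signal-channel gain 0.8);
  single-exponential photobleaching toward an asymptote; white sensor
  noise. Defaults: 6 events/min, amplitude 3 ± 1, noise sd 0.3, motion
  sd 0.5, bleach fraction 15% with τ = 1500 s.
* **Licks**: bout-structured trains whose within-bout intervals are drawn
  from [max(0.15, 0.5/(n−1)), 0.95] s so every scheduled bout satisfies
  the detection rule by construction, with > 1 s gaps between bouts.
* **PSC streams**: piecewise-homogeneous Poisson with a rate step during
  wash-on; gamma amplitudes (CV 0.35).
* **Calibration**: replicate ratios Normal(slope·C + intercept, cv·mean)
  — proportional noise, the regime that motivates 1/C weighting.
* **Counts**: per-gene Bernoulli gating (the expression fraction is the
  gating probability by construction) with 1 + Poisson positive counts.

Not emulated: biophysical indicator dynamics, hemodynamic artifacts,
wavelength-alternating demodulation, lick microstructure beyond bouts,
raw voltage-clamp traces (event detection from current sweeps is out of
scope — the deterministic peak detector replaces interactive software),
chromatographic peak integration, and any real cell-type structure or
gene-gene correlation in the count matrix (co-expression is independent
by construction). Passing tests therefore demonstrate the *analysis
code* is correct under the stated generative assumptions, not that those
assumptions capture every property of real recordings; noise and motion
spectra in particular are stand-ins, exposed as parameters.

## Problem sizes and numerical choices

Benchmarks and the acceptance script run at desk scale on one core:
motion-removal uses 100 sessions of 120 s at the full 1017.25 Hz;
transient recovery uses 50 sessions of 600 s at 200 Hz (downsampled by
20 to the same ~10 Hz effective rate as the full pipeline); the analysis
drivers simulate complete 3.5-h DID sessions at 1017.25/5 Hz with
downsample factor 20, preserving the ~10.17 Hz effective rate of the
full protocol. All seeds derive from one master seed via
`numpy.random.SeedSequence`. Tolerances: z-score contract and
holm-adjustment identities at 1e−9; WLS recovery at 1e−10 relative;
statistical checks at 3σ of their Monte-Carlo error.

## Known limitations

* The isosbestic correction is a single global linear fit; slow drifts
  with channel-specific gains leave a small residual by construction.
* The event detector has a 1 s resolution floor; closely spaced
  transients are reported as one compound event.
* Amplitude values are in per-trace z-units and are not comparable
  across sessions without the within-day W1 reference.
* The LLOQ search does not refit the curve without the evaluated level.
* Expression fractions use count > 0 positivity; an intensity threshold
  would require the normalization pipeline that is deliberately out of
  scope.
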