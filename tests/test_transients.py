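"""Epoch segmentation, transient detection, and the W1-normalized
amplitude-distribution statistics (AUC and peak)."""

import numpy as np
import pytest

from estrocycle.errors import (DataError, DegenerateDataError)
from estrocycle.photometry import EpochInterval, PreprocessConfig, preprocess
from estrocycle.synthetic import PhotometrySimParams, simulate_photometry
from estrocycle.transients import (TransientEvent, amplitude_distribution,
                                   detect_transients, match_events,
                                   segment_epochs, summarize_distribution)


def events_at(times, amps):
    return [TransientEvent(t, a) for t, a in zip(times, amps)]


class TestSegmentEpochs:
    def test_standard_schedule(self, did_schedule):
        eps = segment_epochs(did_schedule)
        got = {e.label: (e.start_s, e.end_s) for e in eps}
        assert got == {"W1": (1800.0, 3600.0), "EtOH1": (3600.0, 5400.0),
                       "EtOH2": (9000.0, 10800.0), "W2": (10800.0, 12600.0)}

    def test_exactly_one_hour_etoh_abuts(self):
        sched = [EpochInterval("W1", 0, 1800),
                 EpochInterval("EtOH", 1800, 5400),
                 EpochInterval("W2", 5400, 7200)]
        eps = {e.label: e for e in segment_epochs(sched)}
        assert eps["EtOH1"].end_s == eps["EtOH2"].start_s == 3600.0

    def test_short_access_rejected(self):
        sched = [EpochInterval("W1", 0, 1200),
                 EpochInterval("EtOH", 1200, 8400),
                 EpochInterval("W2", 8400, 10200)]
        with pytest.raises(DataError):
            segment_epochs(sched)


class TestDetectTransients:
    def test_single_spike_amplitude(self, trace_factory):
        z = np.zeros(1000)
        z[500] = 5.0
        ev = detect_transients(trace_factory(z))
        assert len(ev) == 1
        assert ev[0].amplitude == pytest.approx(5.0, abs=0.01)

    def test_pure_noise_extreme_threshold_silent(self, trace_factory):
        """k_mad = 8 on pure noise yields zero events in >= 95% of runs."""
        silent = 0
        n_runs = 200
        for seed in range(n_runs):
            z = np.random.default_rng(seed).normal(size=2000)
            silent += len(detect_transients(trace_factory(z), k_mad=8.0)) == 0
        assert silent / n_runs >= 0.95

    def test_shift_invariance(self, trace_factory):
        rng = np.random.default_rng(3)
        z = rng.normal(size=3000)
        z[::250] += 6.0
        ev0 = detect_transients(trace_factory(z))
        ev7 = detect_transients(trace_factory(z + 7.0))
        assert [(e.time, round(e.amplitude, 9)) for e in ev0] == \
               [(e.time, round(e.amplitude, 9)) for e in ev7]

    @pytest.mark.parametrize("seed", range(4))
    def test_recovery_on_strong_transients(self, seed):
        """Sensitivity >= 0.95 and FDR <= 0.05 when amplitudes are at least
        five times the sensor noise."""
        p = PhotometrySimParams(duration_s=600, fs=200, seed=seed,
                                transient_rate=6.0, transient_amp_mean=3.0,
                                transient_amp_sd=0.5, noise_sd=0.3,
                                motion_amp=0.3)
        session, gt = simulate_photometry(p)
        tr = preprocess(session, PreprocessConfig(downsample_factor=20,
                                                  start_exclusion_s=0))
        ev = detect_transients(tr)
        m = match_events(ev, gt.transient_times, tol_s=0.5,
                         resolvable_gap_s=1.0)
        assert m["sensitivity"] >= 0.95
        assert m["fdr"] <= 0.05

    def test_empty_trace_rejected(self, trace_factory):
        with pytest.raises(DataError):
            detect_transients(trace_factory(np.empty(0)))


class TestAmplitudeDistribution:
    W1 = EpochInterval("W1", 0.0, 1800.0)
    E1 = EpochInterval("EtOH1", 1800.0, 3600.0)

    def test_reference_self_normalizes_to_one(self):
        ref = events_at([10, 20, 30, 40], [1.2, 2.5, 3.1, 0.8])
        d = amplitude_distribution(ref, self.W1, ref, self.W1)
        assert d.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    def test_binning_by_hand(self):
        ref = events_at([5.0], [1.0])
        ev = events_at([1900, 2000, 2100], [1.2, 1.7, 3.4])
        d = amplitude_distribution(ev, self.E1, ref, self.W1, bin_width=1.0)
        counts = dict(zip(d.bin_edges[:-1], d.counts))
        assert counts[1.0] == 2 and counts[3.0] == 1
        assert d.counts.sum() == 3

    def test_added_large_events_raise_total_and_shift_peak(self):
        rng = np.random.default_rng(0)
        ref = events_at(rng.uniform(0, 1800, 50), rng.normal(2.0, 0.2, 50))
        extra = events_at(rng.uniform(1800, 3600, 10),
                          rng.normal(6.0, 0.1, 10))
        shifted = [TransientEvent(e.time + 1800.0, e.amplitude) for e in ref]
        d_ref = amplitude_distribution(ref, self.W1, ref, self.W1)
        d_aug = amplitude_distribution(shifted + extra, self.E1, ref, self.W1)
        assert d_aug.normalized.sum() > 1.0
        s_ref = summarize_distribution(d_ref)
        s_aug = summarize_distribution(d_aug)
        assert s_aug.auc > s_ref.auc
        assert s_aug.peak_amplitude >= s_ref.peak_amplitude

    def test_zero_reference_rejected(self):
        with pytest.raises(DegenerateDataError):
            amplitude_distribution([], self.E1, [], self.W1)

    def test_counts_additive_over_disjoint_epochs(self):
        rng = np.random.default_rng(1)
        ev = events_at(rng.uniform(0, 3600, 200), rng.uniform(0.5, 5, 200))
        ref = events_at([5.0], [1.0])
        full = EpochInterval("all", 0, 3600)
        d_full = amplitude_distribution(ev, full, ref, self.W1)
        d_a = amplitude_distribution(ev, self.W1, ref, self.W1)
        d_b = amplitude_distribution(ev, self.E1, ref, self.W1)
        np.testing.assert_array_equal(d_full.counts, d_a.counts + d_b.counts)


class TestSummarizeDistribution:
    def test_trapezoid_by_hand(self):
        ref = events_at([1.0], [1.5])
        d = amplitude_distribution(ref, EpochInterval("W1", 0, 60), ref,
                                   EpochInterval("W1", 0, 60), bin_width=1.0,
                                   amp_range=(0.0, 3.0))
        # single event in bin [1,2): normalized = [0, 1, 0]
        s = summarize_distribution(d)
        assert s.peak_amplitude == pytest.approx(1.5)
        assert s.auc == pytest.approx(1.0)

    def test_single_lowest_bin_peak(self):
        ref = events_at([1.0], [0.2])
        d = amplitude_distribution(ref, EpochInterval("W1", 0, 60), ref,
                                   EpochInterval("W1", 0, 60))
        assert summarize_distribution(d).peak_amplitude == pytest.approx(0.25)

    def test_scaling_linearity(self):
        ref = events_at([1, 2, 3], [1.2, 1.4, 2.6])
        ep = EpochInterval("W1", 0, 60)
        d = amplitude_distribution(ref, ep, ref, ep)
        s = summarize_distribution(d)
        d.normalized = d.normalized * 3.0
        s3 = summarize_distribution(d)
        assert s3.auc == pytest.approx(3.0 * s.auc)
        assert s3.peak_amplitude == s.peak_amplitude

    def test_rectangle_and_trapezoid_agree_within_one_bin(self):
        rng = np.random.default_rng(2)
        ep = EpochInterval("W1", 0, 600)
        ev = events_at(rng.uniform(0, 600, 100), rng.gamma(4, 0.5, 100))
        d = amplitude_distribution(ev, ep, ev, ep)
        s = summarize_distribution(d)
        width = d.bin_edges[1] - d.bin_edges[0]
        rect = float(np.sum(d.normalized) * width)
        assert abs(s.auc - rect) <= d.normalized.max() * width


class TestDissociation:
    """Rate-only increases raise the AUC without moving the peak; amplitude
    increases shift the peak by the injected amount."""

    @staticmethod
    def _dist(rate, amp_mean, seed):
        ep = EpochInterval("E", 0, 1800)
        rng = np.random.default_rng(seed)
        n = rng.poisson(rate * 30)
        return events_at(rng.uniform(0, 1800, n),
                         rng.normal(amp_mean, 0.3, n))

    def test_rate_increase_moves_auc_not_peak(self, ):
        ep = EpochInterval("E", 0, 1800)
        ref = self._dist(10, 3.0, 0)
        doubled = self._dist(20, 3.0, 1)
        d_ref = amplitude_distribution(ref, ep, ref, ep)
        d_dbl = amplitude_distribution(doubled, ep, ref, ep)
        s_ref, s_dbl = map(summarize_distribution, (d_ref, d_dbl))
        assert s_dbl.auc > s_ref.auc * 1.5
        assert abs(s_dbl.peak_amplitude - s_ref.peak_amplitude) <= 0.5

    def test_amplitude_shift_moves_peak(self):
        ep = EpochInterval("E", 0, 1800)
        ref = self._dist(10, 3.0, 2)
        shifted = self._dist(10, 5.0, 3)
        d_ref = amplitude_distribution(ref, ep, ref, ep)
        d_shift = amplitude_distribution(shifted, ep, ref, ep)
        s_ref, s_shift = map(summarize_distribution, (d_ref, d_shift))
        assert s_shift.peak_amplitude - s_ref.peak_amplitude == \
            pytest.approx(2.0, abs=0.5)
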