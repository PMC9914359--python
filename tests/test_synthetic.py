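"""Generators: respiratory-rate process, IPFM beat trains, ECG rendering, cohorts."""

import numpy as np
import pytest
from scipy import signal as sps

from edrcomplex import (
    RSAParams,
    RespRateProcess,
    detect_rpeaks,
    inject_ectopic_beats,
    render_ecg,
    simulate_resp_rate_trace,
    simulate_rpeak_train,
)
from edrcomplex.errors import CalibrationError, InvalidArgumentError
from edrcomplex.synthetic import (
    CohortSpec,
    _invert_calibration,
    fit_lognormal_to_median_iqr,
    generate_cohort,
)
from scipy.integrate import cumulative_trapezoid


class TestRespRateTrace:
    def test_zero_modulation_gives_constant_series(self):
        proc = RespRateProcess(base_rate=0.22, modulation_sd=0.0, seed=1)
        tr = simulate_resp_rate_trace(proc, duration=120, fs_out=4)
        assert np.all(tr.rate_hz == 0.22)

    def test_same_seed_is_bit_identical(self):
        proc = RespRateProcess(modulation_sd=0.03, seed=42)
        a = simulate_resp_rate_trace(proc, duration=300, fs_out=8)
        b = simulate_resp_rate_trace(proc, duration=300, fs_out=8)
        assert np.array_equal(a.rate_hz, b.rate_hz)

    def test_stationary_sd_matches_ar1_scaling(self):
        # innovation variance is scaled by (1 - ar^2), so the trace sd should
        # sit near the requested stationary value
        proc = RespRateProcess(modulation_sd=0.05, ar_coefficient=0.9, seed=3)
        tr = simulate_resp_rate_trace(proc, duration=1200, fs_out=8)
        assert abs(tr.rate_hz.std() - 0.05) < 0.3 * 0.05

    def test_rate_stays_positive_and_clipped(self):
        proc = RespRateProcess(base_rate=0.12, modulation_sd=0.2, seed=0)
        tr = simulate_resp_rate_trace(proc, duration=600, fs_out=4)
        assert tr.rate_hz.min() >= 0.05 and tr.rate_hz.max() <= 0.45

    @pytest.mark.parametrize("duration,fs", [(-1, 4), (0, 4), (10, 0.5)])
    def test_invalid_arguments(self, duration, fs):
        with pytest.raises(InvalidArgumentError):
            simulate_resp_rate_trace(RespRateProcess(), duration=duration, fs_out=fs)


class TestIPFM:
    def test_unmodulated_train_is_exactly_periodic(self):
        resp = simulate_resp_rate_trace(
            RespRateProcess(modulation_sd=0.0), duration=120, fs_out=8
        )
        train = simulate_rpeak_train(
            RSAParams(mean_hr=60, rsa_depth=0, hr_jitter_sd=0), resp, 120
        )
        assert np.allclose(np.diff(train.times), 1.0, atol=1e-9)

    def test_beat_count_equals_rate_times_time(self):
        resp = simulate_resp_rate_trace(
            RespRateProcess(modulation_sd=0.0), duration=600, fs_out=8
        )
        train = simulate_rpeak_train(RSAParams(mean_hr=60, rsa_depth=3), resp, 600)
        assert abs(len(train) - 600) <= 2

    def test_ipfm_conserves_integrated_rate(self):
        # number of beats = floor(integral of instantaneous rate) +/- 1
        resp = simulate_resp_rate_trace(
            RespRateProcess(modulation_sd=0.03, seed=9), duration=400, fs_out=8
        )
        rsa = RSAParams(mean_hr=72, rsa_depth=6, hr_jitter_sd=0.0)
        train = simulate_rpeak_train(rsa, resp, 400, seed=5)
        phase = cumulative_trapezoid(resp.rate_hz, resp.times, initial=0.0)
        hr = rsa.mean_hr + rsa.rsa_depth * np.sin(2 * np.pi * phase)
        total_beats = cumulative_trapezoid(hr / 60.0, resp.times, initial=0.0)[-1]
        assert abs(len(train) - np.floor(total_beats)) <= 1

    def test_rsa_modulation_appears_at_respiratory_frequency(self):
        resp = simulate_resp_rate_trace(
            RespRateProcess(base_rate=0.25, modulation_sd=0.0), duration=600, fs_out=8
        )
        train = simulate_rpeak_train(
            RSAParams(mean_hr=70, rsa_depth=5, hr_jitter_sd=0), resp, 600
        )
        inst_rate = 60.0 / np.diff(train.times)
        midpoints = train.times[:-1] + np.diff(train.times) / 2
        grid = np.arange(midpoints[0], midpoints[-1], 0.25)
        resampled = np.interp(grid, midpoints, inst_rate)
        freqs, pxx = sps.periodogram(resampled - resampled.mean(), fs=4.0)
        assert abs(freqs[np.argmax(pxx)] - 0.25) < 0.01

    def test_nonpositive_rate_rejected(self):
        resp = simulate_resp_rate_trace(
            RespRateProcess(modulation_sd=0.0), duration=60, fs_out=8
        )
        with pytest.raises(InvalidArgumentError):
            simulate_rpeak_train(
                RSAParams(mean_hr=10, rsa_depth=5, hr_jitter_sd=20), resp, 60, seed=0
            )


class TestEctopicInjection:
    @pytest.fixture()
    def train(self):
        resp = simulate_resp_rate_trace(
            RespRateProcess(modulation_sd=0.01, seed=2), duration=600, fs_out=8
        )
        return simulate_rpeak_train(RSAParams(mean_hr=70, rsa_depth=4), resp, 600, seed=3)

    def test_zero_rate_is_noop(self, train):
        out, log = inject_ectopic_beats(train, rate=0.0, seed=1)
        assert np.array_equal(out.times, train.times) and len(log) == 0

    def test_perturbation_count_is_poisson_around_rate(self, train):
        counts = [
            len(inject_ectopic_beats(train, rate=2.0, seed=s)[1]) for s in range(30)
        ]
        # 10-min record at 2/min -> mean 20; allow wide Poisson slack on the mean
        assert 15 < np.mean(counts) < 25

    def test_times_remain_strictly_increasing(self, train):
        out, log = inject_ectopic_beats(train, rate=5.0, seed=7)
        assert np.all(np.diff(out.times) > 0)
        assert len(log) > 0


class TestRenderECG:
    def test_sample_count(self, clean_ecg):
        resp = simulate_resp_rate_trace(
            RespRateProcess(modulation_sd=0.0), duration=1200, fs_out=8
        )
        train = simulate_rpeak_train(RSAParams(), resp, 1200)
        ecg = render_ecg(train, fs=128)
        assert len(ecg.samples) == 153_600  # 20 min at 128 Hz

    def test_clean_template_peaks_at_annotations(self, clean_ecg):
        ecg, _ = clean_ecg
        for t in ecg.annotations[5:10]:
            idx = int(round(t * ecg.fs))
            lo, hi = idx - 6, idx + 7
            assert abs(lo + np.argmax(ecg.samples[lo:hi]) - idx) <= 1

    def test_fs_below_qrs_resolution_rejected(self, clean_ecg):
        _, train = clean_ecg
        with pytest.raises(InvalidArgumentError):
            render_ecg(train, fs=50)

    def test_detection_roundtrip_recovers_annotations(self, clean_ecg):
        ecg, _ = clean_ecg
        detected = detect_rpeaks(ecg)
        tol = 1.0 / ecg.fs + 1e-9
        matched = sum(
            np.min(np.abs(detected.times - t)) <= tol for t in ecg.annotations
        )
        assert matched / len(ecg.annotations) >= 0.99


class TestLognormalCalibration:
    def test_median_iqr_round_trip(self):
        mu, sigma, loc = fit_lognormal_to_median_iqr(0.97, 0.22)
        q = loc + np.exp(mu + sigma * np.array([-0.674489750196082, 0, 0.674489750196082]))
        assert abs(q[1] - 0.97) < 1e-12
        assert abs((q[2] - q[0]) - 0.22) < 1e-12

    def test_invalid_targets_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_lognormal_to_median_iqr(0.5, 0.2, loc=0.7)
        with pytest.raises(InvalidArgumentError):
            fit_lognormal_to_median_iqr(1.0, 0.0)

    def test_unattainable_signal_target_raises_calibration_error(self):
        sd_grid = np.array([0.01, 0.02, 0.04])
        apen_grid = np.array([0.2, 0.3, 0.4])
        with pytest.raises(CalibrationError):
            _invert_calibration(0.9, sd_grid, apen_grid)


class TestCohort:
    def test_class_sizes_match_spec(self, cohort):
        sizes = cohort.groupby("group", observed=True).size()
        assert tuple(sizes[g] for g in ("UWS", "MCS", "EMCS")) == (42, 61, 99)

    def test_group_ordering_is_ordinal(self, cohort):
        assert list(cohort["group"].cat.categories) == ["UWS", "MCS", "EMCS"]
        assert cohort["group"].cat.ordered

    def test_degenerate_prevalence_gives_all_present(self):
        spec = CohortSpec(
            group_sizes=(5, 5, 5),
            descriptor_prevalences=((1.0, 1.0, 1.0),) * 3,
            seed=0,
        )
        coh = generate_cohort(spec)
        assert (coh[["frequency_theta", "apg", "reactivity"]] == 1).all().all()

    def test_feature_mode_hits_published_median(self):
        # 10,000 draws from the unresponsive-wakefulness class distribution
        spec = CohortSpec(group_sizes=(10_000, 1, 1), seed=11)
        coh = generate_cohort(spec)
        uws = coh.loc[coh["group"] == "UWS", "apen"]
        assert abs(np.median(uws) - 0.97) < 0.02

    def test_determinism(self):
        a = generate_cohort(CohortSpec(seed=5))
        b = generate_cohort(CohortSpec(seed=5))
        assert a.equals(b)

    def test_etiology_labels_valid(self, cohort):
        assert set(cohort["etiology"]) <= {
            "traumatic",
            "anoxic",
            "ischemic",
            "hemorrhagic",
        }
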