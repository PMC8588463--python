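"""Generator contracts: state profiles, determinism, spectral fidelity,
power bookkeeping and artifact injection."""
from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from drivewave.bands import BAND_NAMES
from drivewave.spectra import band_powers, welch_psd
from drivewave.synth import (
    STATE_PROFILES,
    StateSpec,
    _draw_fractions,
    default_state_specs,
    inject_artifacts,
    synthesize_recording,
)


class TestStateSpecs:
    def test_default_means_match_profiles(self):
        specs = default_state_specs()
        assert set(specs) == {"resting", "city_roadway", "expressway"}
        for state, spec in specs.items():
            for band in BAND_NAMES:
                assert spec.band_relpower_mean[band] == STATE_PROFILES[state][band][0]

    def test_profile_means_sum_to_one_before_normalization(self):
        # hand-summed: e.g. resting 0.124+0.278+0.113+0.344+0.141 = 1.000
        for state, spec in default_state_specs().items():
            raw_sum = sum(spec.band_relpower_mean.values())
            assert raw_sum == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(band_relpower_sd={b: -0.1 for b in BAND_NAMES}),
            dict(band_relpower_mean={b: 0.0 for b in BAND_NAMES}),
            dict(total_power_uV2=-5.0),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        base = dict(
            state="x",
            band_relpower_mean={b: 0.2 for b in BAND_NAMES},
            band_relpower_sd={b: 0.01 for b in BAND_NAMES},
        )
        base.update(bad)
        with pytest.raises(ValueError):
            StateSpec(**base)


class TestSynthesis:
    def test_determinism(self, small_specs):
        sp = small_specs["city_roadway"]
        r1 = synthesize_recording(sp, seed=7, fs=250.0)
        r2 = synthesize_recording(sp, seed=7, fs=250.0)
        assert np.array_equal(r1.data, r2.data)
        assert r1.annotations == r2.annotations
        r3 = synthesize_recording(sp, seed=8, fs=250.0)
        assert not np.array_equal(r1.data, r3.data)

    def test_single_band_spec_concentrates_alpha(self, alpha_only_spec):
        rec = synthesize_recording(alpha_only_spec, seed=0, fs=250.0)
        # measure one non-settle epoch directly on the raw output
        epoch = rec.data[:, 3 * 2500: 4 * 2500]
        psd = welch_psd(epoch, 250.0, rec.channel_names)
        bp = band_powers(psd)
        alpha = bp[(bp.band == "alpha")].rel_power
        assert (alpha >= 0.95).all()

    def test_epoch_variance_matches_total_power(self, small_specs):
        sp = replace(small_specs["city_roadway"], total_power_uV2=250.0)
        rec = synthesize_recording(sp, seed=3, fs=250.0)
        n = 2500
        epochs = rec.data[:, : 9 * n].reshape(4, 9, n)
        var = epochs.var(axis=-1)
        # per-epoch variance fluctuates with the Welch estimator's sampling
        # error (components are scaled by in-band Welch power, not variance)
        assert np.abs(var.mean() / 250.0 - 1) < 0.05
        assert np.abs(var / 250.0 - 1).max() < 0.20

    def test_realized_relative_power_matches_targets(self, small_specs):
        """Per-epoch Welch relative powers track the drawn targets closely."""
        sp = small_specs["city_roadway"]
        rng = np.random.default_rng(5)
        fracs = _draw_fractions(sp, rng)
        rec = synthesize_recording(sp, seed=5, fs=250.0)
        n = 2500
        n_chunks = fracs.shape[1]
        worst = 0.0
        for subj in range(2):
            for ep in range(n_chunks):
                i0 = (subj * n_chunks + ep) * n
                psd = welch_psd(rec.data[:, i0: i0 + n], 250.0, rec.channel_names)
                bp = band_powers(psd)
                for c, ch in enumerate(rec.channel_names):
                    got = (
                        bp[(bp.channel == ch) & (bp.band != "total")]
                        .set_index("band")
                        .rel_power[list(BAND_NAMES)]
                        .to_numpy()
                    )
                    worst = max(worst, np.abs(got - fracs[subj, ep, c]).max())
        assert worst < 0.03

    def test_resting_cohort_mean_delta_recovers_profile(self):
        """17 subjects x 3 epochs: realized global delta near 0.344."""
        spec = default_state_specs()["resting"]
        rec = synthesize_recording(spec, seed=42, fs=250.0)
        n = 2500
        vals = []
        n_chunks = 6  # 30 s settle + 3 feature epochs
        for s in range(spec.n_subjects):
            for ep in range(3, n_chunks):
                i0 = (s * n_chunks + ep) * n
                psd = welch_psd(rec.data[:, i0: i0 + n], 250.0, rec.channel_names)
                bp = band_powers(psd)
                per_ch = bp[(bp.band == "delta")].rel_power.to_numpy()
                vals.append(per_ch.mean())
        assert np.mean(vals) == pytest.approx(0.344, abs=0.05)


class TestFractionDraws:
    @settings(max_examples=10, deadline=None)
    @given(seed=st_.integers(0, 2**31 - 1))
    def test_fractions_are_valid_compositions(self, small_specs, seed):
        sp = small_specs["resting"]
        f = _draw_fractions(sp, np.random.default_rng(seed))
        assert (f > 0).all() and (f < 1).all()
        np.testing.assert_allclose(f.sum(axis=-1), 1.0, atol=1e-9)

    def test_asymmetry_offset_biases_frontal_pair(self, small_specs):
        sp = replace(
            small_specs["resting"], asymmetry_offset={"alpha": 0.08}
        )
        f = _draw_fractions(sp, np.random.default_rng(0))
        alpha = f[..., 2]
        # channel order Fp1, Fp2, O1, O2: right minus left positive
        assert (alpha[:, :, 1] - alpha[:, :, 0]).mean() > 0.05


class TestArtifacts:
    def test_noop_when_all_rates_zero(self, small_cohort):
        res = inject_artifacts(small_cohort, 0.0, 0.0, 0.0, seed=1)
        assert np.array_equal(res.recording.data, small_cohort.data)
        assert res.recording.channels == small_cohort.channels

    def test_line_noise_adds_60hz_peak(self, small_cohort):
        res = inject_artifacts(small_cohort, 0.0, 0.0, 10.0, seed=1)
        from scipy import signal as sg

        f, p0 = sg.welch(small_cohort.data[0], 250.0, nperseg=2500)
        f, p1 = sg.welch(res.recording.data[0], 250.0, nperseg=2500)
        band = (f >= 59) & (f <= 61)
        assert p1[band].sum() > 20 * max(p0[band].sum(), 1e-12)

    def test_blink_count_matches_event_log(self, small_specs):
        rec = synthesize_recording(
            replace(small_specs["resting"], n_subjects=1, epochs_per_subject=3),
            seed=9, fs=250.0,
        )
        res = inject_artifacts(rec, blink_rate_hz=0.25, emg_burst_rate_hz=0.0,
                               line_amp_uV=0.0, seed=4)
        assert "EOG" in res.recording.channel_names
        eog = res.recording.get("EOG")
        fs = res.recording.fs
        # every logged blink leaves a clear transient on the EOG reference
        for t in res.blink_times_s:
            i0 = int(t * fs)
            assert eog[i0: i0 + int(0.5 * fs)].max() > 150.0
        # threshold-counted events match the log up to overlapping blinks
        above = eog > 150.0
        n_events = int(np.sum(np.diff(above.astype(int)) == 1))
        assert 0 < n_events <= len(res.blink_times_s)
        assert n_events >= 0.7 * len(res.blink_times_s)
        # Poisson range sanity: rate 0.25 Hz over 60 s
        assert 0 < len(res.blink_times_s) <= 40

    def test_emg_adds_reference_and_high_freq_power(self, small_cohort):
        res = inject_artifacts(small_cohort, 0.0, 0.5, 0.0, seed=2)
        assert "EMG" in res.recording.channel_names
        assert len(res.emg_times_s) > 0
        assert not np.array_equal(res.recording.data[0], small_cohort.data[0])

    def test_negative_rate_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            inject_artifacts(small_cohort, -1.0, 0.0, 0.0, seed=0)
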