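"""Welch PSD and frequency-domain feature extraction."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from drivewave.bands import BAND_NAMES, BandScheme
from drivewave.spectra import (
    aggregate_channels,
    band_powers,
    extract_features,
    spectral_summaries,
    welch_psd,
)
from tests.conftest import tone_epoch

FS = 250.0


class TestWelch:
    def test_tone_peak_at_its_frequency(self):
        psd = welch_psd(tone_epoch(10.0, FS), FS)
        peak = psd.freqs[np.argmax(psd.power[0])]
        assert abs(peak - 10.0) <= psd.df

    def test_white_noise_is_flat_across_bands(self, rng):
        x = rng.normal(0, 1.0, int(10 * FS))
        psd = welch_psd(x, FS)
        means = []
        for band in BAND_NAMES:
            lo, hi = BandScheme().edges(band)
            m = (psd.freqs >= lo) & (psd.freqs < hi)
            means.append(psd.power[0, m].mean())
        assert max(means) / min(means) < 2.0

    def test_zero_signal_gives_zero_psd(self):
        psd = welch_psd(np.zeros(int(10 * FS)), FS)
        assert np.all(psd.power == 0)

    def test_parseval_consistency(self, rng):
        x = rng.normal(0, 3.0, int(10 * FS))
        psd = welch_psd(x, FS)
        power_integral = psd.power[0].sum() * psd.df
        assert power_integral == pytest.approx(x.var(), rel=0.05)

    def test_nan_epoch_rejected(self):
        x = np.zeros(int(10 * FS))
        x[5] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            welch_psd(x, FS)


class TestBandPowers:
    def test_tone_power_concentrated_in_alpha(self):
        bp = band_powers(welch_psd(tone_epoch(10.0, FS), FS))
        rel = bp.set_index("band").rel_power
        assert rel["alpha"] >= 0.95
        assert all(rel[b] <= 0.05 for b in BAND_NAMES if b != "alpha")

    def test_white_noise_relative_powers_follow_bandwidth(self, rng):
        # flat spectrum: rel power = bandwidth / 43.5
        xs = rng.normal(0, 1.0, (40, int(10 * FS)))
        rels = []
        for x in xs:
            bp = band_powers(welch_psd(x, FS))
            rels.append(bp.set_index("band").rel_power[list(BAND_NAMES)])
        rel = pd.concat(rels, axis=1).mean(axis=1)
        assert rel["delta"] == pytest.approx(3.5 / 43.5, abs=0.01)
        assert rel["beta"] == pytest.approx(17.0 / 43.5, abs=0.02)

    def test_relative_powers_sum_to_one(self, rng):
        x = rng.normal(0, 2.0, (4, int(10 * FS)))
        bp = band_powers(welch_psd(x, FS))
        sums = bp[bp.band != "total"].groupby("channel").rel_power.sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.normal(0, 1.0, int(10 * FS))
        r1 = band_powers(welch_psd(x, FS)).rel_power
        r2 = band_powers(welch_psd(10 * x, FS)).rel_power
        np.testing.assert_allclose(r1, r2, rtol=1e-9)

    def test_zero_power_flagged_as_nan(self):
        bp = band_powers(welch_psd(np.zeros(int(10 * FS)), FS))
        assert bp[bp.band != "total"].rel_power.isna().all()


class TestSummaries:
    def test_tone_collapses_all_summaries(self):
        ss = spectral_summaries(welch_psd(tone_epoch(10.0, FS), FS))
        row = ss[ss.band == "alpha"].iloc[0]
        for col in ("median_freq", "mean_freq", "peak_freq"):
            assert row[col] == pytest.approx(10.0, abs=0.5)
        # the 90% crossing reaches into the neighbour bin because the
        # Hamming main lobe spreads ~13% of a tone into each side bin
        assert row["edge_freq"] == pytest.approx(10.0, abs=0.75)

    def test_flat_alpha_spectrum_quantiles(self):
        # uniform density on [8, 13): median 10.5, 90% edge 12.5
        freqs = np.arange(0.5, 44.0, 0.5)
        power = np.zeros((1, len(freqs)))
        power[0, (freqs >= 8.0) & (freqs < 13.0)] = 1.0
        from drivewave.spectra import PSDEstimate

        ss = spectral_summaries(PSDEstimate(freqs, power, ["Fp1"]))
        row = ss[ss.band == "alpha"].iloc[0]
        assert row.median_freq == pytest.approx(10.5, abs=0.25)
        assert row.edge_freq == pytest.approx(12.5, abs=0.25)

    def test_two_tone_power_weighted_mean(self):
        x = tone_epoch(9.0, FS) + tone_epoch(12.0, FS)
        ss = spectral_summaries(welch_psd(x, FS))
        row = ss[ss.band == "alpha"].iloc[0]
        assert row.mean_freq == pytest.approx(10.5, abs=0.3)

    def test_median_below_edge_within_band(self, rng):
        x = rng.normal(0, 1.0, int(10 * FS))
        ss = spectral_summaries(welch_psd(x, FS))
        assert (ss.median_freq <= ss.edge_freq + 1e-9).all()

    def test_zero_band_reports_missing(self):
        ss = spectral_summaries(welch_psd(np.zeros(int(10 * FS)), FS))
        assert ss.median_freq.isna().all()


class TestAggregates:
    @staticmethod
    def _tidy(values: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(epoch=0, subject="S01", state="resting",
                     channel=ch, band="delta", rel_power=v)
                for ch, v in values.items()
            ]
        )

    def test_frontal_mean(self):
        tidy = self._tidy({"Fp1": 0.4, "Fp2": 0.6, "O1": 0.1, "O2": 0.1})
        out = aggregate_channels(tidy)
        frontal = out[out.channel == "frontal"].rel_power.iloc[0]
        assert frontal == pytest.approx(0.5)

    def test_global_equals_channels_when_identical(self):
        tidy = self._tidy({c: 0.25 for c in ("Fp1", "Fp2", "O1", "O2")})
        out = aggregate_channels(tidy)
        assert out[out.channel == "global"].rel_power.iloc[0] == pytest.approx(0.25)

    def test_global_is_mean_of_four_channels(self):
        tidy = self._tidy({"Fp1": 0.2, "Fp2": 0.2, "O1": 0.4, "O2": 0.4})
        out = aggregate_channels(tidy)
        assert out[out.channel == "global"].rel_power.iloc[0] == pytest.approx(0.3)

    def test_missing_channel_makes_aggregate_nan(self):
        tidy = self._tidy({"Fp1": 0.2, "O1": 0.4, "O2": 0.4})
        out = aggregate_channels(tidy)
        assert np.isnan(out[out.channel == "frontal"].rel_power.iloc[0])
        assert np.isnan(out[out.channel == "global"].rel_power.iloc[0])


class TestOracle:
    def test_welch_band_powers_match_periodogram_sums(self, rng):
        """Independent route: raw periodogram band sums, 100 epochs."""
        from scipy import signal as sg

        n = int(10 * FS)
        welch_tot = np.zeros(len(BAND_NAMES))
        perio_tot = np.zeros(len(BAND_NAMES))
        scheme = BandScheme()
        for _ in range(100):
            x = rng.normal(0, 1.0, n)
            bp = band_powers(welch_psd(x, FS)).set_index("band")
            f, p = sg.periodogram(x, FS)
            for i, band in enumerate(BAND_NAMES):
                lo, hi = scheme.edges(band)
                welch_tot[i] += bp.abs_power[band]
                perio_tot[i] += p[(f >= lo) & (f < hi)].sum() * (f[1] - f[0])
        np.testing.assert_allclose(welch_tot, perio_tot, rtol=0.05)


def test_extract_features_layout(small_tidy):
    channels = {"Fp1", "Fp2", "O1", "O2", "frontal", "occipital", "global"}
    assert set(small_tidy.channel) == channels
    assert set(small_tidy.band) == set(BAND_NAMES) | {"total"}
    # per-state mean relative powers are a composition: sum to 1
    g = small_tidy[(small_tidy.channel == "global") & (small_tidy.band != "total")]
    sums = g.groupby(["state", "band"]).rel_power.mean().groupby("state").sum()
    np.testing.assert_allclose(sums, 1.0, atol=0.01)
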