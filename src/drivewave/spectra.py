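"""Welch power spectra and frequency-domain features per epoch.

Each 10-s epoch is reduced to a one-sided Welch PSD (Hamming-windowed 2-s
segments, 50% overlap, 0.5 Hz resolution) and then to per-band features:
absolute and relative band power, mean power density, and the median /
power-weighted mean / 90% spectral-edge / peak frequencies.  Channel
aggregates (frontal = mean of Fp1+Fp2, occipital = O1+O2, global = all
four) are unweighted means of the per-channel feature values.

PSD bins are treated as uniform power mass over ``[f, f + df)``; quantile
crossings (median, spectral edge) are interpolated linearly inside a bin,
and the power-weighted mean frequency uses bin centres.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import (
    DEFAULT_SCHEME,
    FRONTAL_CHANNELS,
    OCCIPITAL_CHANNELS,
    BandScheme,
)
from .recording import Epochs

__all__ = [
    "PSDEstimate",
    "welch_psd",
    "band_powers",
    "spectral_summaries",
    "aggregate_channels",
    "extract_features",
    "SpectralFeatureExtractor",
]

AGGREGATES = {
    "frontal": list(FRONTAL_CHANNELS),
    "occipital": list(OCCIPITAL_CHANNELS),
    "global": list(FRONTAL_CHANNELS) + list(OCCIPITAL_CHANNELS),
}

FREQ_FEATURES = ("median_freq", "mean_freq", "edge_freq", "peak_freq")
POWER_FEATURES = ("abs_power", "rel_power", "mean_power")


@dataclass
class PSDEstimate:
    """One-sided PSD on a uniform grid, power in uV^2/Hz."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.power.ndim != 2 or self.power.shape[1] != len(self.freqs):
            raise ValueError("power must be (n_channels, n_freqs)")
        if (self.power < 0).any():
            raise ValueError("PSD must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(
    epoch: np.ndarray,
    fs: float,
    channel_names: list[str] | None = None,
    segment_s: float = 2.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PSDEstimate:
    """Welch PSD of one epoch, shape (n_channels, n_samples) or (n_samples,)."""
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    if np.isnan(x).any():
        raise ValueError("epoch contains NaNs")
    nperseg = int(round(segment_s * fs))
    if x.shape[1] < nperseg:
        raise ValueError(
            f"epoch of {x.shape[1]} samples shorter than one Welch segment"
        )
    freqs, power = signal.welch(
        x, fs, window=window, nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), detrend="constant", axis=-1,
    )
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(x.shape[0])]
    return PSDEstimate(freqs, power, list(channel_names))


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)


def band_powers(
    psd: PSDEstimate, scheme: BandScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Absolute, relative and mean band power per channel.

    Relative power divides by the total power over the scheme's full range,
    so relative powers sum to exactly 1 per channel.  Mean power is band
    power divided by band width (a density, uV^2/Hz).  A zero-power channel
    yields NaN relative powers (flagged for downstream exclusion).
    """
    df = psd.df
    rows = []
    total = np.zeros(len(psd.channel_names))
    band_abs = {}
    for band in scheme.names:
        lo, hi = scheme.edges(band)
        m = _band_mask(psd.freqs, lo, hi)
        p = psd.power[:, m].sum(axis=1) * df
        band_abs[band] = p
        total += p
    with np.errstate(invalid="ignore", divide="ignore"):
        for band in scheme.names:
            lo, hi = scheme.edges(band)
            p = band_abs[band]
            rel = np.where(total > 0, p / total, np.nan)
            for c, ch in enumerate(psd.channel_names):
                rows.append(
                    dict(
                        channel=ch, band=band,
                        abs_power=p[c], rel_power=rel[c],
                        mean_power=p[c] / (hi - lo),
                    )
                )
        for c, ch in enumerate(psd.channel_names):
            rows.append(
                dict(
                    channel=ch, band="total",
                    abs_power=total[c],
                    rel_power=1.0 if total[c] > 0 else np.nan,
                    mean_power=total[c]
                    / (scheme.total_range[1] - scheme.total_range[0]),
                )
            )
    return pd.DataFrame(rows)


def _quantile_crossing(
    freqs: np.ndarray, mass: np.ndarray, df: float, q: float
) -> float:
    """Frequency below which fraction q of the mass lies (bins = [f, f+df))."""
    cum = np.cumsum(mass)
    target = q * cum[-1]
    k = int(np.searchsorted(cum, target))
    if k >= len(mass):
        return float(freqs[-1] + df)
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (target - prev) / mass[k] if mass[k] > 0 else 0.0
    return float(freqs[k] + frac * df)


def spectral_summaries(
    psd: PSDEstimate, scheme: BandScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Within-band frequency summaries per channel.

    median = 50% cumulative-power crossing, edge = 90% crossing,
    mean = power-weighted mean frequency (bin centres), peak = argmax bin.
    Zero-power bands report NaN.
    """
    df = psd.df
    rows = []
    for band in scheme.names:
        lo, hi = scheme.edges(band)
        m = _band_mask(psd.freqs, lo, hi)
        f = psd.freqs[m]
        for c, ch in enumerate(psd.channel_names):
            p = psd.power[c, m]
            tot = p.sum()
            if tot <= 0:
                med = mean = edge = peak = np.nan
            else:
                med = _quantile_crossing(f, p, df, 0.5)
                edge = _quantile_crossing(f, p, df, 0.9)
                mean = float(((f + df / 2) * p).sum() / tot)
                peak = float(f[int(np.argmax(p))])
            rows.append(
                dict(
                    channel=ch, band=band,
                    median_freq=med, mean_freq=mean,
                    edge_freq=edge, peak_freq=peak,
                )
            )
    return pd.DataFrame(rows)


def aggregate_channels(features: pd.DataFrame) -> pd.DataFrame:
    """Append frontal/occipital/global rows as means of per-channel values.

    Operates on any tidy frame with a ``channel`` column; every numeric
    feature column is averaged over the constituent channels (missing
    channels make the aggregate NaN).
    """
    group_cols = [
        c for c in ("epoch", "subject", "state", "band") if c in features.columns
    ]
    value_cols = [
        c for c in features.columns
        if c not in group_cols + ["channel"]
        and pd.api.types.is_numeric_dtype(features[c])
    ]
    out = [features]
    for agg, members in AGGREGATES.items():
        sub = features[features["channel"].isin(members)]
        if sub.empty:
            continue
        if group_cols:
            g = sub.groupby(group_cols, observed=True, sort=False)
            means = g[value_cols].mean(), g["channel"].nunique()
            agg_df = means[0].reset_index()
            counts = means[1].reset_index(name="_n")
            agg_df = agg_df.merge(counts, on=group_cols)
        else:
            agg_df = sub[value_cols].mean().to_frame().T
            agg_df["_n"] = sub["channel"].nunique()
        agg_df.loc[agg_df["_n"] < len(members), value_cols] = np.nan
        agg_df = agg_df.drop(columns="_n")
        agg_df["channel"] = agg
        out.append(agg_df)
    return pd.concat(out, ignore_index=True)[features.columns.tolist()]


def extract_features(
    epochs: Epochs,
    scheme: BandScheme = DEFAULT_SCHEME,
    segment_s: float = 2.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> pd.DataFrame:
    """Tidy per-epoch spectral feature table.

    One row per (epoch, channel-or-aggregate, band incl. 'total') with
    power and frequency features; epoch index, subject and state labels
    attached.
    """
    frames = []
    for i in range(epochs.n_epochs):
        psd = welch_psd(
            epochs.data[i], epochs.fs, epochs.channel_names,
            segment_s=segment_s, overlap=overlap, window=window,
        )
        bp = band_powers(psd, scheme)
        ss = spectral_summaries(psd, scheme)
        tidy = bp.merge(ss, on=["channel", "band"], how="left")
        tidy.insert(0, "epoch", i)
        tidy.insert(1, "subject", epochs.subject[i])
        tidy.insert(2, "state", epochs.state[i])
        frames.append(tidy)
    allf = pd.concat(frames, ignore_index=True)
    return aggregate_channels(allf)


class SpectralFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer wrapper over `extract_features` for pipeline composition.

    ``transform`` accepts an `Epochs` object and returns the tidy feature
    frame; stateless (``fit`` records the band scheme only).
    """

    def __init__(
        self,
        scheme: BandScheme = DEFAULT_SCHEME,
        segment_s: float = 2.0,
        overlap: float = 0.5,
        window: str = "hamming",
    ):
        self.scheme = scheme
        self.segment_s = segment_s
        self.overlap = overlap
        self.window = window

    def fit(self, X: Epochs, y=None) -> "SpectralFeatureExtractor":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Epochs) -> pd.DataFrame:
        return extract_features(
            X, self.scheme, self.segment_s, self.overlap, self.window
        )
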