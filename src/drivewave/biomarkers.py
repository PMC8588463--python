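"""Composite workload biomarkers and the canonical 149-column feature table.

Biomarkers derived from the spectral features:

* resting baseline: per-subject arithmetic mean of each feature over that
  subject's resting epochs,
* relative change from baseline: (e - r) / r, stored as a fraction,
* frontal asymmetry: (right - left) / (right + left) per band for the
  frontal electrode pair (Fp2 right, Fp1 left),
* DAR = e_delta / e_alpha and DTR = e_delta / e_theta, the delta-alpha and
  delta-theta power ratios (identical whether computed from relative or
  absolute powers, since the normalizing total cancels).

The feature table has exactly 149 columns: per-channel band features
(4 channels x 5 bands x 5 features = 100), global band mean power (5),
frontal/occipital band mean power (10) plus their baseline changes (10),
per-channel DAR/DTR (8) plus changes (8), per-channel total mean power (4)
plus changes (4).
"""
from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, EEG_CHANNELS

__all__ = [
    "feature_columns",
    "resting_baseline",
    "relative_change",
    "asymmetry",
    "delta_ratios",
    "build_feature_table",
    "frontal_asymmetry",
    "RESTING_STATE",
]

#: State label treated as the baseline condition.
RESTING_STATE = "resting"

_FEAT_SHORT = {
    "mean_power": "meanpow",
    "median_freq": "medfreq",
    "mean_freq": "meanfreq",
    "edge_freq": "edge",
    "peak_freq": "peakfreq",
}

LOBES = ("frontal", "occipital")


def feature_columns() -> list[str]:
    """The 149 feature column names, in canonical order."""
    cols: list[str] = []
    for ch in EEG_CHANNELS:
        for band in BAND_NAMES:
            for feat in _FEAT_SHORT.values():
                cols.append(f"{ch}_{band}_{feat}")
    cols += [f"global_{band}_meanpow" for band in BAND_NAMES]
    for lobe in LOBES:
        cols += [f"{lobe}_{band}_meanpow" for band in BAND_NAMES]
    for lobe in LOBES:
        cols += [f"{lobe}_{band}_meanpow_chg" for band in BAND_NAMES]
    for ch in EEG_CHANNELS:
        cols += [f"{ch}_dar", f"{ch}_dtr"]
    for ch in EEG_CHANNELS:
        cols += [f"{ch}_dar_chg", f"{ch}_dtr_chg"]
    cols += [f"{ch}_total_meanpow" for ch in EEG_CHANNELS]
    cols += [f"{ch}_total_meanpow_chg" for ch in EEG_CHANNELS]
    assert len(cols) == 149
    return cols


class DeltaRatios(NamedTuple):
    dar: float
    dtr: float


def relative_change(value, baseline):
    """Change relative to a baseline, (e - r)/r, as a fraction.

    Multiply by 100 for display as percent.  A zero baseline yields NaN
    with a warning.
    """
    value = np.asarray(value, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    bad = baseline == 0
    if np.any(bad):
        warnings.warn("zero baseline: relative change undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, (value - baseline) / baseline)
    return out if out.ndim else float(out)


def asymmetry(e_right, e_left):
    """Hemispheric asymmetry index (right - left)/(right + left) in [-1, 1]."""
    e_right = np.asarray(e_right, dtype=float)
    e_left = np.asarray(e_left, dtype=float)
    denom = e_right + e_left
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (e_right - e_left) / denom, np.nan)
    return out if out.ndim else float(out)


def delta_ratios(e_delta, e_theta, e_alpha) -> DeltaRatios:
    """Delta-alpha (DAR) and delta-theta (DTR) power ratios.

    Scale-invariant: relative or absolute band powers give the same
    ratios.  Zero denominators yield NaN.
    """
    e_delta = np.asarray(e_delta, dtype=float)
    e_theta = np.asarray(e_theta, dtype=float)
    e_alpha = np.asarray(e_alpha, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dar = np.where(e_alpha > 0, e_delta / e_alpha, np.nan)
        dtr = np.where(e_theta > 0, e_delta / e_theta, np.nan)
    if dar.ndim == 0:
        return DeltaRatios(float(dar), float(dtr))
    return DeltaRatios(dar, dtr)


def resting_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject baseline profile from resting epochs.

    ``table`` is any frame with ``subject`` and ``state`` columns; the
    result holds, per subject, the arithmetic mean of every numeric column
    over that subject's resting epochs, plus ``n_epochs``.
    """
    rest = table[table["state"] == RESTING_STATE]
    if rest.empty:
        raise ValueError("no resting epochs to build a baseline from")
    num_cols = [
        c for c in rest.columns
        if c not in ("subject", "state", "epoch")
        and pd.api.types.is_numeric_dtype(rest[c])
    ]
    base = rest.groupby("subject")[num_cols].mean()
    base["n_epochs"] = rest.groupby("subject").size()
    return base


def _wide_from_tidy(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy spectral frame to one row per epoch."""
    feats = list(_FEAT_SHORT)
    per_ch = tidy[tidy["channel"].isin(EEG_CHANNELS)]
    key = ["epoch", "subject", "state"]
    pieces = {}

    band_rows = per_ch[per_ch["band"] != "total"]
    for feat in feats:
        p = band_rows.pivot_table(
            index=key, columns=["channel", "band"], values=feat, sort=False
        )
        for ch, band in p.columns:
            pieces[f"{ch}_{band}_{_FEAT_SHORT[feat]}"] = p[(ch, band)]

    # aggregates: mean power per band
    for agg in ("global",) + LOBES:
        rows = tidy[(tidy["channel"] == agg) & (tidy["band"] != "total")]
        p = rows.pivot_table(index=key, columns="band", values="mean_power",
                             sort=False)
        for band in p.columns:
            pieces[f"{agg}_{band}_meanpow"] = p[band]

    # per-channel DAR/DTR from relative band powers
    relp = band_rows.pivot_table(
        index=key, columns=["channel", "band"], values="rel_power", sort=False
    )
    for ch in EEG_CHANNELS:
        dar, dtr = delta_ratios(
            relp[(ch, "delta")], relp[(ch, "theta")], relp[(ch, "alpha")]
        )
        pieces[f"{ch}_dar"] = pd.Series(dar, index=relp.index)
        pieces[f"{ch}_dtr"] = pd.Series(dtr, index=relp.index)

    # per-channel total mean power
    totals = per_ch[per_ch["band"] == "total"].pivot_table(
        index=key, columns="channel", values="mean_power", sort=False
    )
    for ch in EEG_CHANNELS:
        pieces[f"{ch}_total_meanpow"] = totals[ch]

    wide = pd.DataFrame(pieces)
    wide.index.names = key
    return wide.reset_index()


#: Base columns from which baseline-change columns are derived.
_CHG_BASES = (
    [f"{lobe}_{band}_meanpow" for lobe in LOBES for band in BAND_NAMES]
    + [f"{ch}_{r}" for ch in EEG_CHANNELS for r in ("dar", "dtr")]
    + [f"{ch}_total_meanpow" for ch in EEG_CHANNELS]
)


def build_feature_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Assemble the canonical 149-column feature table from tidy features.

    Baseline-change columns (``*_chg``) are computed per subject against
    that subject's resting baseline of the same feature; subjects without
    resting epochs get NaN changes.
    """
    wide = _wide_from_tidy(tidy)
    base = resting_baseline(wide) if (wide["state"] == RESTING_STATE).any() else None
    for col in _CHG_BASES:
        chg = f"{col}_chg"
        if base is None or col not in base.columns:
            wide[chg] = np.nan
            continue
        ref = wide["subject"].map(base[col])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wide[chg] = relative_change(wide[col].to_numpy(), ref.to_numpy())
    cols = feature_columns()
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise ValueError(f"feature table incomplete, missing: {missing[:5]}...")
    return wide[["epoch", "subject", "state"] + cols]


def frontal_asymmetry(tidy: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch frontal asymmetry index per band (Fp2 right vs Fp1 left)."""
    rows = tidy[
        tidy["channel"].isin(["Fp1", "Fp2"]) & (tidy["band"] != "total")
    ]
    p = rows.pivot_table(
        index=["epoch", "subject", "state"], columns=["channel", "band"],
        values="rel_power", sort=False,
    )
    out = {}
    for band in BAND_NAMES:
        out[band] = asymmetry(
            p[("Fp2", band)].to_numpy(), p[("Fp1", band)].to_numpy()
        )
    res = pd.DataFrame(out, index=p.index)
    return res.reset_index()
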