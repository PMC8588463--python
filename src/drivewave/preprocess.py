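"""Raw EEG cleaning and epoching.

Stage order: 60 Hz notch -> anti-aliased downsample to 250 Hz ->
reference-guided ICA artifact removal (optional) -> zero-phase 0.5-44 Hz
band-pass -> per-segment 30 s settle-period trim -> non-overlapping 10-s
epochs.  All filters are applied forward-backward (zero phase) so that
later asymmetry measures are not biased by phase distortion.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .recording import Epochs, Recording

log = logging.getLogger("drivewave.preprocess")

__all__ = [
    "PreprocessConfig",
    "preprocess",
    "remove_artifacts_ica",
    "estimate_snr",
    "segment_epochs",
    "IcaConvergenceError",
    "SnrEstimate",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering/segmentation parameters.

    Defaults: 60 Hz notch (Q=30), downsample to 250 Hz behind a 100 Hz
    anti-aliasing low-pass, 4th-order Butterworth band-pass 0.5-44 Hz,
    drop the first 30 s of every task segment, 10-s epochs.
    """

    notch_hz: float = 60.0
    notch_q: float = 30.0
    target_fs: float = 250.0
    aa_cutoff_hz: float = 100.0
    bandpass: tuple[float, float] = (0.5, 44.0)
    bp_order: int = 4
    drop_initial_s: float = 30.0
    epoch_s: float = 10.0
    ica_enabled: bool = True
    ica_correlation_threshold: float = 0.7

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not (0 < lo < hi < self.target_fs / 2):
            raise ValueError("need bandpass low < high < target_fs/2")
        if self.epoch_s <= 0 or self.drop_initial_s < 0:
            raise ValueError("epoch_s must be > 0 and drop_initial_s >= 0")
        if not (0 < self.ica_correlation_threshold <= 1):
            raise ValueError("ica_correlation_threshold must be in (0, 1]")


class IcaConvergenceError(RuntimeError):
    """FastICA failed to converge within its iteration budget."""


class SnrEstimate(NamedTuple):
    ratio: float
    db: float


def preprocess(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Notch, downsample and band-pass a raw recording.

    Returns a new recording at ``cfg.target_fs``; the input is unmodified.
    All channels (EEG and references) pass through the same chain so they
    stay time-aligned for ICA.
    """
    lo, hi = cfg.bandpass
    if rec.fs < 2 * hi:
        raise ValueError(
            f"sampling rate {rec.fs} Hz below Nyquist for band-pass high {hi} Hz"
        )
    if rec.duration_s < cfg.drop_initial_s + cfg.epoch_s:
        raise ValueError(
            f"recording of {rec.duration_s:.1f}s shorter than settle period "
            f"+ one epoch ({cfg.drop_initial_s + cfg.epoch_s:.1f}s)"
        )
    x = rec.data
    fs = rec.fs
    if cfg.notch_hz and fs > 2 * cfg.notch_hz:
        b, a = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=fs)
        x = signal.filtfilt(b, a, x, axis=-1)
    if fs != cfg.target_fs:
        factor = fs / cfg.target_fs
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                f"fs {fs} is not an integer multiple of target {cfg.target_fs}"
            )
        factor = int(round(factor))
        if factor > 1:
            sos = signal.butter(8, cfg.aa_cutoff_hz, fs=fs, output="sos")
            x = signal.sosfiltfilt(sos, x, axis=-1)
            x = x[:, ::factor]
        fs = cfg.target_fs
    sos_bp = signal.butter(
        cfg.bp_order, [lo, hi], btype="bandpass", fs=fs, output="sos"
    )
    x = signal.sosfiltfilt(sos_bp, x, axis=-1)
    log.info(
        "stage=preprocess level=info msg=filtered fs=%g->%g rms=%.2f",
        rec.fs, fs, float(np.sqrt(np.mean(x**2))),
    )
    return Recording(list(rec.channels), fs, x, list(rec.annotations))


def remove_artifacts_ica(
    rec: Recording,
    eog: str | None = "EOG",
    emg: str | None = "EMG",
    cfg: PreprocessConfig = PreprocessConfig(),
    max_iter: int = 1000,
    seed: int = 0,
) -> Recording:
    """Reference-guided FastICA artifact removal.

    EEG channels are decomposed into as many independent components as
    there are EEG channels; any component whose absolute Pearson
    correlation with the EOG or EMG reference exceeds
    ``cfg.ica_correlation_threshold`` is zeroed before reconstruction.
    If no component crosses the threshold the input is returned unchanged
    (with a warning).
    """
    eeg_idx = rec.indices_by_role("eeg")
    if len(eeg_idx) < 4:
        raise ValueError("ICA needs at least 4 EEG channels")
    refs = []
    for name in (eog, emg):
        if name is not None and name in rec.channel_names:
            refs.append(rec.get(name))
    if not refs:
        warnings.warn("no reference channels found; skipping ICA")
        return rec.copy()
    X = rec.data[eeg_idx].T  # (n_samples, n_eeg)
    ica = FastICA(
        n_components=len(eeg_idx),
        whiten="unit-variance",
        max_iter=max_iter,
        tol=1e-4,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            S = ica.fit_transform(X)
        except ConvergenceWarning as exc:
            raise IcaConvergenceError(
                f"FastICA did not converge in {max_iter} iterations"
            ) from exc
    drop = []
    for k in range(S.shape[1]):
        for ref in refs:
            r = np.corrcoef(S[:, k], ref)[0, 1]
            if abs(r) > cfg.ica_correlation_threshold:
                drop.append(k)
                break
    if not drop:
        warnings.warn("no ICA component exceeded the correlation threshold")
        return rec.copy()
    log.info(
        "stage=ica level=info msg=removed components=%s n_iter=%d",
        drop, ica.n_iter_,
    )
    S_clean = S.copy()
    S_clean[:, drop] = 0.0
    X_hat = ica.inverse_transform(S_clean)
    out = rec.copy()
    out.data[eeg_idx] = X_hat.T
    return out


def estimate_snr(disturbed: np.ndarray, clean: np.ndarray) -> SnrEstimate:
    """Power ratio of a disturbed signal to its undisturbed counterpart."""
    disturbed = np.asarray(disturbed, dtype=float)
    clean = np.asarray(clean, dtype=float)
    if disturbed.shape != clean.shape:
        raise ValueError("signals must have equal length")
    p_clean = float(np.mean(clean**2))
    if p_clean == 0:
        raise ValueError("clean signal has zero power")
    ratio = float(np.mean(disturbed**2)) / p_clean
    return SnrEstimate(ratio, 10.0 * np.log10(ratio) if ratio > 0 else -np.inf)


def segment_epochs(
    rec: Recording, cfg: PreprocessConfig = PreprocessConfig()
) -> Epochs:
    """Cut annotated segments into labelled non-overlapping epochs.

    Per segment the first ``drop_initial_s`` are discarded, then
    consecutive ``epoch_s`` windows are cut; a trailing partial window is
    dropped.  Segments too short for a single epoch yield zero epochs with
    a warning.
    """
    if not rec.annotations:
        raise ValueError("recording has no annotations to segment")
    eeg_idx = rec.indices_by_role("eeg")
    n_samp = int(round(cfg.epoch_s * rec.fs))
    chunks, states, subjects = [], [], []
    for ann in rec.annotations:
        usable = ann.duration_s - cfg.drop_initial_s
        n_ep = int(np.floor(usable / cfg.epoch_s)) if usable > 0 else 0
        if n_ep <= 0:
            warnings.warn(
                f"segment ({ann.state}, {ann.subject}) of {ann.duration_s:.0f}s "
                "too short for any epoch after the settle period"
            )
            continue
        i0 = int(round((ann.start_s + cfg.drop_initial_s) * rec.fs))
        for k in range(n_ep):
            sl = slice(i0 + k * n_samp, i0 + (k + 1) * n_samp)
            chunks.append(rec.data[eeg_idx, sl])
            states.append(ann.state)
            subjects.append(ann.subject)
    if not chunks:
        data = np.empty((0, len(eeg_idx), n_samp))
    else:
        data = np.stack(chunks)
    names = [rec.channels[i][0] for i in eeg_idx]
    return Epochs(data, rec.fs, names, np.array(states), np.array(subjects))
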