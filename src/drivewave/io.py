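"""Readers and writers: long-format CSV and EDF recordings, feature tables.

CSV recording dialect (long format): one row per sample per channel with
columns ``channel, role, time_s, value_uV, state, subject``; time is
seconds from the start of the recording and must be uniform per channel.
State/subject cells are empty outside annotated segments.

EDF reading goes through MNE; writing uses a minimal EDF+ writer (16-bit,
1-s records, annotations as EDF+ TALs with description "state/subject").
Feature tables are plain CSV at 6 significant digits with a JSON sidecar
(``<name>.meta.json``) carrying provenance (package version, seed, config
hash).
"""
from __future__ import annotations

import json

from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Annotation, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "write_table",
    "read_table",
]

REQUIRED_EEG = ("Fp1", "Fp2", "O1", "O2")


def _check_required(names: list[str]) -> None:
    missing = [c for c in REQUIRED_EEG if c not in names]
    if missing:
        raise ValueError(f"recording is missing required EEG channels: {missing}")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _write_csv(rec: Recording, path: Path) -> None:
    frames = []
    t = np.arange(rec.n_samples) / rec.fs
    state = np.full(rec.n_samples, "", dtype=object)
    subject = np.full(rec.n_samples, "", dtype=object)
    for ann in rec.annotations:
        i0 = int(round(ann.start_s * rec.fs))
        i1 = int(round(ann.end_s * rec.fs))
        state[i0:i1] = ann.state
        subject[i0:i1] = ann.subject
    for i, (name, role) in enumerate(rec.channels):
        frames.append(
            pd.DataFrame(
                dict(
                    channel=name, role=role, time_s=t,
                    value_uV=rec.data[i], state=state, subject=subject,
                )
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.6g"
    )


def _read_csv(path: Path) -> Recording:
    df = pd.read_csv(path, keep_default_na=False, dtype={"state": str, "subject": str})
    needed = {"channel", "role", "time_s", "value_uV", "state", "subject"}
    if not needed <= set(df.columns):
        raise ValueError(f"CSV is missing columns: {sorted(needed - set(df.columns))}")
    channels, data = [], []
    fs = None
    ref_t = None
    for name in df["channel"].drop_duplicates():
        sub = df[df["channel"] == name]
        t = sub["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0:
            raise ValueError(f"channel {name} has a single sample")
        bad = np.nonzero(np.abs(dt - dt[0]) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"non-uniform timestamps for channel {name}: first bad row "
                f"at index {int(bad[0]) + 1} (t={t[bad[0] + 1]})"
            )
        ch_fs = 1.0 / dt[0]
        if fs is None:
            fs, ref_t = ch_fs, t
        elif abs(ch_fs - fs) > 1e-6 or len(t) != len(ref_t):
            raise ValueError(
                f"inconsistent sampling for channel {name}: fs {ch_fs} vs {fs}"
            )
        channels.append((str(name), str(sub["role"].iloc[0])))
        data.append(sub["value_uV"].to_numpy(dtype=float))
    names = [n for n, _ in channels]
    _check_required(names)
    first = df[df["channel"] == names[0]]
    annotations = _runs_to_annotations(
        first["state"].to_numpy(), first["subject"].to_numpy(), fs
    )
    return Recording(channels, fs, np.vstack(data), annotations)


def _runs_to_annotations(state, subject, fs) -> list[Annotation]:
    out = []
    n = len(state)
    i = 0
    while i < n:
        if state[i] == "":
            i += 1
            continue
        j = i
        while j < n and state[j] == state[i] and subject[j] == subject[i]:
            j += 1
        out.append(Annotation(i / fs, (j - i) / fs, str(state[i]), str(subject[i])))
        i = j
    return out


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF+C writer: 16-bit samples, 1-s records, TAL annotations."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record per signal
    n_rec = int(np.ceil(rec.n_samples / spr))
    nsig = len(rec.channels)

    # physical scaling per channel
    pmins, pmaxs, scaled = [], [], []
    for i in range(nsig):
        x = rec.data[i]
        pmin = float(min(x.min(), -1.0))
        pmax = float(max(x.max(), 1.0))
        dig = np.round(
            (x - pmin) / (pmax - pmin) * 65535.0 - 32768.0
        ).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        pad_n = n_rec * spr - len(dig)
        if pad_n:
            dig = np.concatenate([dig, np.zeros(pad_n, dtype="<i2")])
        scaled.append(dig)

    # TALs: timestamp per record, all annotations placed in record 0
    tals = []
    for ann in rec.annotations:
        text = f"{ann.state}/{ann.subject}"
        tals.append(
            f"+{ann.start_s:g}\x15{ann.duration_s:g}\x14{text}\x14\x00".encode()
        )
    ann0 = b"+0\x14\x14\x00" + b"".join(tals)
    ann_bytes = max(len(ann0) + 2, 64)
    ann_spr = (ann_bytes + 1) // 2  # 2-byte samples

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate 01-JAN-2000 X drivewave X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 * (nsig + 2)), 8))
        f.write(_pad("EDF+C", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(nsig + 1), 4))

        labels = [name for name, _ in rec.channels] + ["EDF Annotations"]
        f.write(b"".join(_pad(lb, 16) for lb in labels))
        f.write(b"".join(_pad("", 80) for _ in labels))
        f.write(b"".join(_pad(d, 8) for d in ["uV"] * nsig + [""]))
        f.write(b"".join(_pad(f"{v:.8g}"[:8], 8) for v in pmins + [-1.0]))
        f.write(b"".join(_pad(f"{v:.8g}"[:8], 8) for v in pmaxs + [1.0]))
        f.write(b"".join(_pad("-32768", 8) for _ in labels))
        f.write(b"".join(_pad("32767", 8) for _ in labels))
        f.write(b"".join(_pad("", 80) for _ in labels))
        f.write(b"".join(_pad(str(n), 8) for n in [spr] * nsig + [ann_spr]))
        f.write(b"".join(_pad("", 32) for _ in labels))

        for r in range(n_rec):
            for i in range(nsig):
                f.write(scaled[i][r * spr: (r + 1) * spr].tobytes())
            if r == 0:
                tal = ann0
            else:
                tal = f"+{r}\x14\x14\x00".encode()
            f.write(tal + b"\x00" * (2 * ann_spr - len(tal)))


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = list(raw.ch_names)
    _check_required([n for n in names])
    channels = []
    for n in names:
        role = "eog" if n.upper().startswith("EOG") else (
            "emg" if n.upper().startswith("EMG") else "eeg"
        )
        channels.append((n, role))
    data = raw.get_data() * 1e6  # MNE returns volts
    annotations = []
    for ann in raw.annotations:
        desc = ann["description"]
        state, _, subject = desc.partition("/")
        annotations.append(
            Annotation(float(ann["onset"]), float(ann["duration"]), state, subject)
        )
    return Recording(channels, float(raw.info["sfreq"]), data, annotations)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("edf", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF or long-format CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_recording(
    rec: Recording, path: str | Path, format: str | None = None
) -> Path:
    """Write a recording as EDF or long-format CSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> Path:
    """Write a feature/report table (CSV, 6 significant digits) + sidecar."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
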