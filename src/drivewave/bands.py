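"""Canonical EEG frequency bands and the band scheme used throughout.

Band edges follow the clinical convention: delta 0.5-4 Hz, theta 4-8 Hz,
alpha 8-13 Hz, beta 13-30 Hz, gamma 30-44 Hz.  Bands are half-open
``[low, high)`` so the edges tile the 0.5-44 Hz analysis range without
double counting (a component at exactly 4.0 Hz is theta, not delta).
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous set of half-open frequency bands.

    Parameters
    ----------
    bands
        Mapping band name -> (low, high) in Hz.  Insertion order is the
        canonical band order.
    total_range
        (low, high) in Hz; the denominator range for relative power.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    total_range: tuple[float, float] = (0.5, 44.0)

    def __post_init__(self) -> None:
        lows = [lo for lo, _ in self.bands.values()]
        highs = [hi for _, hi in self.bands.values()]
        for (lo, hi) in self.bands.values():
            if not lo < hi:
                raise ValueError(f"band with low {lo} >= high {hi}")
        # contiguity: each band starts where the previous one ends
        for prev_hi, nxt_lo in zip(highs[:-1], lows[1:]):
            if abs(prev_hi - nxt_lo) > 1e-12:
                raise ValueError("bands must be contiguous and ordered")
        if abs(lows[0] - self.total_range[0]) > 1e-12 or abs(
            highs[-1] - self.total_range[1]
        ) > 1e-12:
            raise ValueError("bands must tile total_range exactly")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        return self.bands[name]


DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 44.0),
}

BAND_NAMES = list(DEFAULT_BANDS)

DEFAULT_SCHEME = BandScheme()

#: EEG channel montage used by the study design this package models:
#: two frontal (Fp1 left, Fp2 right) and two occipital (O1 left, O2 right)
#: electrodes of the 10-20 system.
EEG_CHANNELS = ("Fp1", "Fp2", "O1", "O2")
FRONTAL_CHANNELS = ("Fp1", "Fp2")
OCCIPITAL_CHANNELS = ("O1", "O2")
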