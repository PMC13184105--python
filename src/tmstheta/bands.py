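"""Frequency-band/time-window definitions and electrode selection rules.

The theta and gamma windows and the fixed fronto-central theta electrode set
encode the study's regions of interest; the gamma electrode is chosen per
stimulation site by peak in-window power.  Band membership uses closed
frequency intervals on the grid and half-open time intervals
``[t_lo, t_hi)`` keyed by bin center.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .timefreq import TFMap

__all__ = [
    "BandWindow",
    "default_bands",
    "theta_electrodes",
    "freq_mask",
    "time_mask",
    "roi_average",
    "select_gamma_electrode",
    "band_mean",
]

THETA_ELECTRODES = ("FC1", "FCz", "FC2", "C1", "Cz", "C2")


@dataclass(frozen=True)
class BandWindow:
    """A frequency band paired with a post-stimulus time window."""

    name: str
    f_lo: float
    f_hi: float
    t_lo: float
    t_hi: float

    def __post_init__(self):
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be < f_hi")
        if not self.t_lo < self.t_hi:
            raise ValueError("t_lo must be < t_hi")


def default_bands() -> dict:
    """The study's bands: theta 4-7.5 Hz / 60-300 ms, gamma 30-45 Hz / 20-100 ms."""
    return {
        "theta": BandWindow("theta", 4.0, 7.5, 60.0, 300.0),
        "gamma": BandWindow("gamma", 30.0, 45.0, 20.0, 100.0),
    }


def theta_electrodes() -> tuple:
    """Fixed fronto-central electrode set for the theta analysis."""
    return THETA_ELECTRODES


def freq_mask(freqs: np.ndarray, band: BandWindow) -> np.ndarray:
    """Boolean mask of grid frequencies with ``f_lo <= f <= f_hi``."""
    freqs = np.asarray(freqs)
    return (freqs >= band.f_lo) & (freqs <= band.f_hi)


def time_mask(times: np.ndarray, band: BandWindow) -> np.ndarray:
    """Boolean mask of bin centers with ``t_lo <= t < t_hi``."""
    times = np.asarray(times)
    return (times >= band.t_lo) & (times < band.t_hi)


def roi_average(tf: TFMap, electrodes) -> TFMap:
    """Average a channel-resolved map over an electrode set.

    Raises if the map's montage is missing any requested electrode.
    """
    if tf.channels is None:
        raise ValueError("map has no channel axis")
    missing = [e for e in electrodes if e not in tf.channels]
    if missing:
        raise ValueError(f"montage is missing required channel(s): {', '.join(missing)}")
    idx = [tf.channels.index(e) for e in electrodes]
    return replace(tf, power=tf.power[idx].mean(axis=0), channels=None)


def band_mean(tf: TFMap, band: BandWindow) -> float | np.ndarray:
    """Mean power over the band's frequencies and time window.

    Returns a scalar for ROI maps and one value per channel otherwise.
    """
    fm = freq_mask(tf.freqs, band)
    tm = time_mask(tf.times, band)
    if not fm.any() or not tm.any():
        raise ValueError(f"band {band.name!r} selects no grid cells")
    sub = tf.power[..., fm, :][..., tm]
    out = sub.mean(axis=(-2, -1))
    return float(out) if out.ndim == 0 else out


def select_gamma_electrode(tf: TFMap, band: BandWindow) -> str:
    """Channel with maximal mean band power in the gamma window.

    Expects a dB-scaled channel-resolved map.  Ties break by montage order
    (first maximum).
    """
    if tf.channels is None:
        raise ValueError("gamma electrode selection needs a channel-resolved map")
    if tf.scale != "dB":
        raise ValueError("gamma electrode selection expects a dB-scaled map")
    means = band_mean(tf, band)
    return tf.channels[int(np.argmax(means))]
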