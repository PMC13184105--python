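"""Synthetic TMS-EEG cohort generation.

Emulates the statistical structure the downstream analysis assumes: for each
subject and stimulation site, epochs are built as 1/f background noise plus a
phase-locked ERP, a fronto-central theta burst whose amplitude depends on
group and site, and a small central gamma burst.  Burst phases are uniform
per trial, so the oscillatory response is largely induced; the ERP is
identical across trials (phase-locked).

Amplitudes are specified operationally in decibels: for a requested
elevation ``d`` the injected burst power is scaled so that the analytic
pipeline-expected dB map, averaged over the band's frequencies, time window,
and electrode set, equals ``d``.  The expected noise power under the Morlet
analysis is computed in closed form from the synthesis spectrum and the
band-pass response, so calibration carries no sampling error.

Clinical item scores are generated with group-dependent base rates and a
configurable negative coupling to each subject's theta amplitude deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.optimize import brentq

from . import bands as _bands
from .timefreq import EpochSet, make_freq_grid, _morlet_kernel

__all__ = [
    "GROUPS",
    "DEFAULT_SITES",
    "DEFAULT_CHANNELS",
    "BurstSpec",
    "CohortSpec",
    "Cohort",
    "simulate_cohort",
    "simulate_null_cohort",
    "iter_epoch_sets",
    "simulate_band_power_table",
    "channel_positions",
    "topography_weights",
]

GROUPS = ("HC", "CHR")
DEFAULT_SITES = ("lDLPFC", "lPPC", "DMPFC")

# BrainCap-style 64-channel 10-10 montage (all labels resolvable in the
# standard_1005 montage shipped with mne).
DEFAULT_CHANNELS = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "TP10", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "F9", "F10",
)

# per-site topography center of the gamma burst (central electrodes)
GAMMA_CENTERS = {"lDLPFC": "C1", "lPPC": "C1", "DMPFC": "Cz"}
THETA_CENTER = "FCz"

CLINICAL_ITEMS = ("P1", "P2", "P3", "P4", "P5", "N1", "N2", "N3", "N4", "N5", "N6")

# group-level base means / SDs used for clinical score generation
_ITEM_BASE = {
    "CHR": {"P1": 2.6, "P2": 2.4, "P3": 0.5, "P4": 3.3, "P5": 0.8,
            "N1": 1.8, "N2": 2.8, "N3": 2.0, "N4": 3.3, "N5": 0.6, "N6": 2.5},
    "HC": {"P1": 0.09, "P2": 0.02, "P3": 0.0, "P4": 0.66, "P5": 0.09,
           "N1": np.nan, "N2": np.nan, "N3": np.nan,
           "N4": np.nan, "N5": np.nan, "N6": np.nan},
}
_CONTINUOUS = {  # name -> (CHR mean, CHR sd, HC mean, HC sd, lo, hi)
    "COPER": (11.8, 9.6, 0.1, 0.4, 0.0, None),
    "COGDIS": (8.4, 7.7, 0.0, 0.1, 0.0, None),
    "SOFAS": (59.7, 10.2, 87.8, 4.8, 0.0, 100.0),
    "AVLT_first": (46.9, 27.8, 70.9, 21.8, 0.0, 100.0),
    "AVLT_total": (50.6, 33.7, 74.7, 22.5, 0.0, 100.0),
    "AVLT_delay": (44.7, 32.9, 69.8, 22.0, 0.0, 100.0),
    "DSST": (10.8, 5.8, 12.6, 2.7, 0.0, None),
}


@dataclass(frozen=True)
class BurstSpec:
    """Gaussian-windowed sinusoidal burst: center/duration in ms, carrier Hz.

    The Gaussian envelope has ``sigma = duration / 6`` so the burst's
    effective support is the stated duration.
    """

    center_ms: float
    duration_ms: float
    freq_hz: float

    @property
    def sigma_ms(self) -> float:
        return self.duration_ms / 6.0

    def envelope(self, times_ms: np.ndarray) -> np.ndarray:
        return np.exp(-((times_ms - self.center_ms) ** 2) / (2.0 * self.sigma_ms**2))


def _default_theta_amp() -> dict:
    # HC: differentiated by site (strongest lDLPFC, then lPPC, then DMPFC);
    # CHR: flattened, uniformly elevated near the HC lDLPFC level.
    return {
        "HC": {"lDLPFC": 3.0, "lPPC": 1.6, "DMPFC": 1.4},
        "CHR": {"lDLPFC": 2.9, "lPPC": 2.9, "DMPFC": 2.9},
    }


def _default_gamma_amp() -> dict:
    # small central gamma burst, no group or site differences
    return {g: {s: 1.0 for s in DEFAULT_SITES} for g in GROUPS}


def _default_clinical_effect() -> dict:
    # item-score points per dB of a subject's theta amplitude deviation
    return {"P1": -0.8, "N2": -0.8, "N4": -0.8, "N6": -1.0}


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort."""

    n_hc: int = 20
    n_chr: int = 20
    sites: tuple = DEFAULT_SITES
    epochs_per_site: int = 100
    sampling_rate: float = 2500.0
    epoch_window: tuple = (-1000.0, 1000.0)
    channels: tuple = DEFAULT_CHANNELS
    theta_amp_db: dict = field(default_factory=_default_theta_amp)
    theta_burst: BurstSpec = BurstSpec(180.0, 240.0, 5.5)
    gamma_amp_db: dict = field(default_factory=_default_gamma_amp)
    gamma_burst: BurstSpec = BurstSpec(60.0, 80.0, 38.0)
    erp_amp: float = 5.0
    noise_exponent: float = 1.0
    noise_rms: float = 10.0
    subject_sd_db: float = 0.5
    clinical_effect: dict = field(default_factory=_default_clinical_effect)
    topo_radius_m: float = 0.09
    seed: int = 0

    def __post_init__(self):
        self.sites = tuple(self.sites)
        self.channels = tuple(self.channels)
        if self.n_hc < 1 or self.n_chr < 1:
            raise ValueError("each group needs at least one subject")
        if self.epochs_per_site < 1:
            raise ValueError("epochs_per_site must be >= 1")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("sites must be distinct")
        t0, t1 = self.epoch_window
        if not (t0 <= -400.0 and t1 >= 300.0):
            raise ValueError(
                "epoch window must contain the baseline [-400, -200] ms and "
                "the theta window [60, 300] ms"
            )
        missing = [c for c in _bands.THETA_ELECTRODES if c not in self.channels]
        if missing:
            raise ValueError(
                f"montage is missing required theta electrode(s): {', '.join(missing)}"
            )
        for name, amp in (("theta_amp_db", self.theta_amp_db),
                          ("gamma_amp_db", self.gamma_amp_db)):
            for g in GROUPS:
                if g not in amp or any(s not in amp[g] for s in self.sites):
                    raise ValueError(f"{name} must cover every group x site cell")
        if not isinstance(self.theta_burst, BurstSpec):
            self.theta_burst = BurstSpec(*self.theta_burst)
        if not isinstance(self.gamma_burst, BurstSpec):
            self.gamma_burst = BurstSpec(*self.gamma_burst)

    @property
    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) / 1000.0 * self.sampling_rate))
        return t0 + np.arange(n) / self.sampling_rate * 1000.0

    @property
    def subjects(self) -> tuple:
        hc = tuple(f"HC{i + 1:03d}" for i in range(self.n_hc))
        chr_ = tuple(f"CHR{i + 1:03d}" for i in range(self.n_chr))
        return hc + chr_

    def group_of(self, subject: str) -> str:
        return "HC" if subject.startswith("HC") else "CHR"


@dataclass
class Cohort:
    """Materialized cohort: epoch sets, clinical table, generator truth."""

    epochs: dict                 # subject -> site -> EpochSet
    clinical: pd.DataFrame       # one row per subject
    truth: pd.DataFrame          # one row per subject x site
    spec: CohortSpec


# ---------------------------------------------------------------------------
# montage geometry
# ---------------------------------------------------------------------------

_MONTAGE_POS: dict = {}


def channel_positions(channels) -> dict:
    """3-D positions (m) of 10-10 labels from the standard montage."""
    if not _MONTAGE_POS:
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            mont = mne.channels.make_standard_montage("standard_1005")
        _MONTAGE_POS.update(mont.get_positions()["ch_pos"])
    missing = [c for c in channels if c not in _MONTAGE_POS]
    if missing:
        raise ValueError(f"labels not in the 10-05 montage: {', '.join(missing)}")
    return {c: np.asarray(_MONTAGE_POS[c], dtype=float) for c in channels}


def topography_weights(channels, center: str, radius_m: float = 0.09) -> np.ndarray:
    """Cosine falloff with scalp distance from a center electrode.

    ``w = cos(pi/2 * d / radius)`` clipped to zero beyond ``radius``; the
    center channel has weight 1.
    """
    pos = channel_positions(tuple(channels) + ((center,) if center not in channels else ()))
    c = pos[center]
    d = np.array([np.linalg.norm(pos[ch] - c) for ch in channels])
    w = np.cos(np.pi / 2.0 * np.minimum(d / radius_m, 1.0))
    return np.clip(w, 0.0, None)


# ---------------------------------------------------------------------------
# noise synthesis
# ---------------------------------------------------------------------------

def _noise_spectrum_sigma(n_samples: int, sfreq: float, exponent: float,
                          rms: float) -> np.ndarray:
    """Per-rfft-bin amplitude sigma for 1/f noise with expected RMS ``rms``.

    Bin ``k`` (k >= 1) receives a complex coefficient ``sigma_k * (a + ib)``
    with a, b standard normal; DC is zero.  The overall scale is chosen
    analytically so the expected time-domain RMS equals ``rms``.
    """
    n_r = n_samples // 2 + 1
    f = np.arange(n_r) * sfreq / n_samples
    sigma = np.zeros(n_r)
    sigma[1:] = f[1:] ** (-exponent / 2.0)
    # E[sum x^2] = (1/S) * sum_k E|X_k|^2 over the full (Hermitian) spectrum
    e_full = 2.0 * sigma**2
    weight = np.full(n_r, 2.0)
    weight[0] = 1.0
    if n_samples % 2 == 0:
        weight[-1] = 1.0
    exp_ms = (weight * e_full).sum() / n_samples**2  # expected mean square
    return sigma * (rms / np.sqrt(exp_ms))


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                      sfreq: float, exponent: float, rms: float) -> np.ndarray:
    """1/f noise, iid across the leading axes, via spectral synthesis."""
    sigma = _noise_spectrum_sigma(n_samples, sfreq, exponent, rms)
    n_r = sigma.size
    coef = rng.standard_normal(shape + (n_r,)) + 1j * rng.standard_normal(shape + (n_r,))
    coef *= sigma
    coef[..., 0] = 0.0
    if n_samples % 2 == 0:
        coef[..., -1] = coef[..., -1].real
    return np.fft.irfft(coef, n=n_samples, axis=-1)


# ---------------------------------------------------------------------------
# dB amplitude calibration
# ---------------------------------------------------------------------------

def _bandpass_sos(sfreq: float, lo: float = 3.0, hi: float = 100.0) -> np.ndarray:
    sos_hp = sp_signal.butter(6, 0.8 * lo, "highpass", fs=sfreq, output="sos")
    sos_lp = sp_signal.butter(6, 1.1 * hi, "lowpass", fs=sfreq, output="sos")
    return np.vstack([sos_hp, sos_lp])


def _expected_noise_power(spec: CohortSpec, freqs, cycles) -> np.ndarray:
    """Analytic Morlet power of the band-passed 1/f noise, per frequency.

    Sums the synthesis spectrum times the (forward-backward) filter power
    response times the wavelet's power transfer, over the synthesis bins.
    """
    times = spec.times
    n_s = times.size
    sigma = _noise_spectrum_sigma(n_s, spec.sampling_rate, spec.noise_exponent,
                                  spec.noise_rms)
    # fold to the full DFT circle: the wavelet is analytic (one-sided), so
    # positive- and negative-frequency bins must be summed separately
    fold = np.minimum(np.arange(n_s), n_s - np.arange(n_s))
    e_x2 = 2.0 * sigma[fold] ** 2  # E|X_k|^2, Hermitian-symmetric
    bin_f = fold * spec.sampling_rate / n_s
    sos = _bandpass_sos(spec.sampling_rate)
    _, h = sp_signal.sosfreqz(sos, worN=2.0 * np.pi * bin_f / spec.sampling_rate)
    gain2 = np.abs(h) ** 4  # filtfilt applies the filter twice
    out = np.empty(len(freqs))
    for i, (f, c) in enumerate(zip(freqs, cycles)):
        kern = _morlet_kernel(f, c, spec.sampling_rate)
        # DTFT of the kernel at every bin k/n_s: fold the kernel modulo n_s
        folded = np.zeros(n_s, dtype=complex)
        np.add.at(folded, np.arange(len(kern)) % n_s, kern)
        K = np.fft.fft(folded)
        out[i] = (e_x2 * gain2 * np.abs(K) ** 2).sum() / n_s**2
    return out


def _unit_burst_power(spec: CohortSpec, burst: BurstSpec, freqs, cycles) -> np.ndarray:
    """Morlet power map of a unit-amplitude burst after band-passing.

    Averaged over four carrier phases so per-trial random phase is matched
    in expectation.  Shape ``(n_freqs, n_samples)``.
    """
    times = spec.times
    env = burst.envelope(times)
    sos = _bandpass_sos(spec.sampling_rate)
    out = np.zeros((len(freqs), times.size))
    phases = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
    for phi in phases:
        x = env * np.cos(2 * np.pi * burst.freq_hz * times / 1000.0 + phi)
        x = sp_signal.sosfiltfilt(sos, x)
        for i, (f, c) in enumerate(zip(freqs, cycles)):
            kern = _morlet_kernel(f, c, spec.sampling_rate)
            y = np.convolve(x, kern, mode="same")
            out[i] += (y.real**2 + y.imag**2) / len(phases)
    return out


@dataclass
class _BandCalibration:
    """Precomputed quantities to map a dB target to a burst amplitude."""

    ratio: np.ndarray        # (n_channels_roi, n_freqs, n_window_samples)

    def solve(self, target_db: float) -> float:
        """Amplitude (at the topography center) achieving the dB target."""
        if target_db <= 0.0:
            return 0.0

        def g(s):
            return np.mean(10.0 * np.log10(1.0 + s * self.ratio)) - target_db

        hi = 1.0
        while g(hi) < 0:
            hi *= 4.0
            if hi > 1e12:
                raise RuntimeError("calibration failed to bracket the target")
        s = brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-10)
        return float(np.sqrt(s))


def _calibrate_band(spec: CohortSpec, burst: BurstSpec, band: _bands.BandWindow,
                    weights_roi: np.ndarray) -> _BandCalibration:
    grid = make_freq_grid()
    fm = _bands.freq_mask(grid.freqs, band)
    freqs, cycles = grid.freqs[fm], grid.cycles[fm]
    p_noise = _expected_noise_power(spec, freqs, cycles)
    p_burst = _unit_burst_power(spec, burst, freqs, cycles)
    times = spec.times
    tm = (times >= band.t_lo) & (times < band.t_hi)
    ratio = (
        weights_roi[:, None, None] ** 2
        * p_burst[None, :, tm]
        / p_noise[None, :, None]
    )
    return _BandCalibration(ratio=ratio)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _erp_waveform(times_ms: np.ndarray) -> np.ndarray:
    """N100/P200-like biphasic deflection with unit N100 magnitude."""
    n100 = -np.exp(-((times_ms - 100.0) ** 2) / (2.0 * 20.0**2))
    p200 = 0.7 * np.exp(-((times_ms - 200.0) ** 2) / (2.0 * 35.0**2))
    return n100 + p200


def _amp_map_is_zero(amp: dict) -> bool:
    return all(v == 0 for g in amp.values() for v in g.values())


def _subject_site_rng(spec: CohortSpec, i_subj: int, i_site: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, i_subj, i_site))
    )


def _draw_truth(spec: CohortSpec):
    """Per-subject random effects and per-cell amplitude targets/scales."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    subjects = spec.subjects
    u = rng.normal(0.0, spec.subject_sd_db, size=len(subjects))

    bands = _bands.default_bands()
    w_theta = topography_weights(spec.channels, THETA_CENTER, spec.topo_radius_m)
    roi_idx = [spec.channels.index(c) for c in _bands.THETA_ELECTRODES]
    calib_theta = None
    if not _amp_map_is_zero(spec.theta_amp_db):
        calib_theta = _calibrate_band(
            spec, spec.theta_burst, bands["theta"], w_theta[roi_idx]
        )
    calib_gamma = None
    if not _amp_map_is_zero(spec.gamma_amp_db):
        # gamma is calibrated at its topography-center electrode (weight 1),
        # which is also the electrode the peak-power selector should find
        calib_gamma = _calibrate_band(
            spec, spec.gamma_burst, bands["gamma"], np.array([1.0])
        )

    rows = []
    for i, subj in enumerate(subjects):
        g = spec.group_of(subj)
        for site in spec.sites:
            d_t = spec.theta_amp_db[g][site] + (u[i] if spec.theta_amp_db[g][site] != 0 else 0.0)
            d_g = spec.gamma_amp_db[g][site] + (u[i] if spec.gamma_amp_db[g][site] != 0 else 0.0)
            a_t = calib_theta.solve(d_t) if calib_theta is not None else 0.0
            a_g = calib_gamma.solve(d_g) if calib_gamma is not None else 0.0
            rows.append(
                {"subject": subj, "group": g, "site": site, "u_db": u[i],
                 "theta_db_target": d_t if calib_theta is not None else 0.0,
                 "theta_amp": a_t,
                 "gamma_db_target": d_g if calib_gamma is not None else 0.0,
                 "gamma_amp": a_g}
            )
    truth = pd.DataFrame(rows)
    return truth, u


def _make_epoch_set(spec: CohortSpec, subj: str, site: str, i_subj: int,
                    i_site: int, theta_amp: float, gamma_amp: float,
                    w_theta: np.ndarray, w_gamma: np.ndarray) -> EpochSet:
    rng = _subject_site_rng(spec, i_subj, i_site)
    times = spec.times
    n_s = times.size
    n_ch = len(spec.channels)
    n_ep = spec.epochs_per_site
    data = _one_over_f_noise(
        rng, (n_ep, n_ch), n_s, spec.sampling_rate, spec.noise_exponent, spec.noise_rms
    )
    if spec.erp_amp != 0:
        data += spec.erp_amp * w_theta[None, :, None] * _erp_waveform(times)[None, None, :]
    t_s = times / 1000.0
    if theta_amp != 0:
        env = spec.theta_burst.envelope(times)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_ep)
        carrier = np.cos(2 * np.pi * spec.theta_burst.freq_hz * t_s[None, :] + phi[:, None])
        data += theta_amp * w_theta[None, :, None] * (env[None, :] * carrier)[:, None, :]
    if gamma_amp != 0:
        env = spec.gamma_burst.envelope(times)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_ep)
        carrier = np.cos(2 * np.pi * spec.gamma_burst.freq_hz * t_s[None, :] + phi[:, None])
        data += gamma_amp * w_gamma[None, :, None] * (env[None, :] * carrier)[:, None, :]
    return EpochSet(
        data=data.astype(np.float32),
        channels=spec.channels,
        sfreq=spec.sampling_rate,
        times=times,
        subject=subj,
        site=site,
        group=spec.group_of(subj),
    )


def iter_epoch_sets(spec: CohortSpec, truth: pd.DataFrame | None = None,
                    subjects=None):
    """Yield one EpochSet per subject x site without materializing the cohort.

    ``subjects`` optionally restricts generation to a subset; per-stream
    seeding makes the yielded epochs identical either way.
    """
    if truth is None:
        truth, _ = _draw_truth(spec)
    keep = None if subjects is None else set(subjects)
    w_theta = topography_weights(spec.channels, THETA_CENTER, spec.topo_radius_m)
    w_gamma_by_site = {
        site: topography_weights(spec.channels, GAMMA_CENTERS.get(site, "Cz"),
                                 spec.topo_radius_m)
        for site in spec.sites
    }
    t = truth.set_index(["subject", "site"])
    for i, subj in enumerate(spec.subjects):
        if keep is not None and subj not in keep:
            continue
        for j, site in enumerate(spec.sites):
            row = t.loc[(subj, site)]
            yield _make_epoch_set(
                spec, subj, site, i, j,
                float(row["theta_amp"]), float(row["gamma_amp"]),
                w_theta, w_gamma_by_site[site],
            )


def _clinical_table(spec: CohortSpec, u: np.ndarray) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,)))
    rows = []
    for i, subj in enumerate(spec.subjects):
        g = spec.group_of(subj)
        row = {"subject": subj, "group": g}
        if g == "CHR":
            row["age"] = float(np.clip(rng.normal(19.2, 4.2), 14.0, 33.0))
            row["antipsychotic"] = bool(rng.random() < 7 / 44)
            row["mood_comorbidity"] = bool(rng.random() < 0.4)
        else:
            row["age"] = float(np.clip(rng.normal(20.2, 3.6), 14.0, 33.0))
            row["antipsychotic"] = False
            row["mood_comorbidity"] = False
        for item in CLINICAL_ITEMS:
            base = _ITEM_BASE[g][item]
            if np.isnan(base):
                row[item] = np.nan
                continue
            slope = spec.clinical_effect.get(item, 0.0)
            val = base + slope * u[i] + rng.normal(0.0, 0.8)
            val = float(np.clip(np.round(val), 0, 6))
            # occasional missing negative-symptom ratings
            if item.startswith("N") and g == "CHR" and rng.random() < 2 / 44:
                val = np.nan
            row[item] = val
        for name, (m_c, s_c, m_h, s_h, lo, hi) in _CONTINUOUS.items():
            m, s = (m_c, s_c) if g == "CHR" else (m_h, s_h)
            slope = spec.clinical_effect.get(name, 0.0)
            val = rng.normal(m, s) + slope * u[i]
            if lo is not None:
                val = max(val, lo)
            if hi is not None:
                val = min(val, hi)
            row[name] = float(val)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort (epochs, clinical table, truth).

    Fully reproducible from ``spec.seed``; every subject x site stream is
    seeded independently so results do not depend on generation order.
    Materializes all epochs in memory — for large cohorts prefer
    :func:`iter_epoch_sets` or :func:`tmstheta.io.save_cohort_hdf5`.
    """
    truth, u = _draw_truth(spec)
    epochs: dict = {}
    for es in iter_epoch_sets(spec, truth):
        epochs.setdefault(es.subject, {})[es.site] = es
    clinical = _clinical_table(spec, u)
    return Cohort(epochs=epochs, clinical=clinical, truth=truth, spec=spec)


def simulate_null_cohort(spec: CohortSpec) -> Cohort:
    """Simulate with all group x site effect maps forced equal.

    Every cell of the theta and gamma amplitude maps is replaced by the
    across-cell mean of the corresponding map, making the generative
    distribution exchangeable across sites and groups.
    """
    return simulate_cohort(null_spec(spec))


def null_spec(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with flattened (exchangeable) effect maps."""

    def flatten(amp: dict) -> dict:
        cells = [amp[g][s] for g in GROUPS for s in spec.sites]
        m = float(np.mean(cells))
        return {g: {s: m for s in spec.sites} for g in GROUPS}

    return dataclasses.replace(
        spec,
        theta_amp_db=flatten(spec.theta_amp_db),
        gamma_amp_db=flatten(spec.gamma_amp_db),
    )


# ---------------------------------------------------------------------------
# table-level simulation for mixed-model validation
# ---------------------------------------------------------------------------

def simulate_band_power_table(
    n_per_group: int = 50,
    beta_site: dict | None = None,
    beta_group: float = 0.0,
    beta_interaction: dict | None = None,
    beta_age: float = 0.0,
    beta_med: float = 0.0,
    intercept: float = 3.0,
    subject_sd: float = 0.5,
    resid_sd: float = 0.5,
    sites: tuple = DEFAULT_SITES,
    band: str = "theta",
    seed=None,
) -> pd.DataFrame:
    """Draw a band-power table directly from a known linear mixed model.

    The reference levels are HC and the first site.  ``beta_site`` and
    ``beta_interaction`` map non-reference sites to fixed effects (a missing
    site gets 0).  Useful for parameter-recovery and calibration checks of
    the model-fitting code without simulating any EEG.
    """
    rng = np.random.default_rng(seed)
    beta_site = beta_site or {}
    beta_interaction = beta_interaction or {}
    rows = []
    for g, n in (("HC", n_per_group), ("CHR", n_per_group)):
        for i in range(n):
            subj = f"{g}{i + 1:03d}"
            age = rng.normal(20.0, 4.0)
            med = bool(rng.random() < 0.15) if g == "CHR" else False
            u = rng.normal(0.0, subject_sd)
            is_chr = 1.0 if g == "CHR" else 0.0
            mood = bool(rng.random() < 0.4) if g == "CHR" else False
            for site in sites:
                mu = (
                    intercept
                    + beta_site.get(site, 0.0)
                    + beta_group * is_chr
                    + beta_interaction.get(site, 0.0) * is_chr
                    + beta_age * age
                    + beta_med * med
                    + u
                )
                rows.append(
                    {"subject": subj, "group": g, "site": site, "band": band,
                     "mean_power": mu + rng.normal(0.0, resid_sd),
                     "age": age, "antipsychotic": med, "mood_comorbidity": mood}
                )
    return pd.DataFrame(rows)
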