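"""Classical EEG preprocessing and feature extraction.

This branch feeds the baseline classifiers: per-channel zero-mean/unit-variance
normalization, a 0.5-45 Hz zero-phase band-pass (4th-order Butterworth applied
forward-backward), autoregressive coefficients fitted by Yule-Walker, and Welch
power spectral densities integrated over the five classical EEG bands
(delta 0.5-4, theta 4-7.5, alpha 8-13, beta 14-30, gamma 30-45 Hz).

The deep models consume raw segments; only the baselines use this branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from statsmodels.regression.linear_model import yule_walker

from .eeg_io import EEGRecording
from .segment import SegmentBatch

__all__ = [
    "ARModel",
    "PSDEstimate",
    "FeatureVector",
    "CLASSICAL_BANDS",
    "zero_mean_normalize",
    "bandpass",
    "ar_coefficients",
    "welch_psd",
    "band_powers",
    "extract_features",
]

CLASSICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class ARModel:
    """Autoregressive model x(n) = c + sum_i a_i x(n-i) + e(n)."""

    order: int
    intercept: float
    coefficients: np.ndarray
    innovation_variance: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != self.order:
            raise ValueError(
                f"{self.coefficients.size} coefficients for order {self.order}"
            )


@dataclass
class PSDEstimate:
    """One-sided Welch power spectral density."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        f, p = np.asarray(self.frequencies, float), np.asarray(self.power, float)
        if f.size != p.size:
            raise ValueError("frequency and power grids differ in length")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(p < -1e-15):
            raise ValueError("negative power")
        self.frequencies, self.power = f, np.maximum(p, 0.0)

    def band_power(self, low: float, high: float) -> float:
        """Integrate the density over [low, high] Hz (trapezoid rule)."""
        mask = (self.frequencies >= low) & (self.frequencies <= high)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.power[mask], self.frequencies[mask]))


@dataclass
class FeatureVector:
    """Concatenated per-channel AR + band-power features with labels."""

    values: np.ndarray
    subject_id: int
    class_id: int


class DegenerateChannelError(ValueError):
    """A channel has zero variance and cannot be standardized."""


def zero_mean_normalize(rec: EEGRecording) -> EEGRecording:
    """Standardize each channel: (x - mean) / population std.

    Reduces intra-subject amplitude variance ahead of the classical pipeline.
    A constant channel has no scale and raises DegenerateChannelError.
    """
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel")
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)  # population (ddof=0)
    dead = np.flatnonzero(sd[:, 0] == 0)
    if dead.size:
        names = ", ".join(rec.channel_names[i] for i in dead)
        raise DegenerateChannelError(f"zero-variance channel(s): {names}")
    return EEGRecording(
        data=(rec.data - mu) / sd,
        fs=rec.fs,
        subject_id=rec.subject_id,
        task_id=rec.task_id,
        channel_names=list(rec.channel_names),
    )


def bandpass(rec: EEGRecording, low: float = 0.5, high: float = 45.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass, default 0.5-45 Hz.

    Applied forward-backward (filtfilt), so pass-band phase is untouched.
    """
    nyq = rec.fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    sos = _signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = _signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(
        data=out,
        fs=rec.fs,
        subject_id=rec.subject_id,
        task_id=rec.task_id,
        channel_names=list(rec.channel_names),
    )


def ar_coefficients(x: np.ndarray, p: int) -> ARModel:
    """Fit an AR(p) model to a 1-D series by Yule-Walker.

    The series is demeaned before fitting; the intercept is recovered as
    mean * (1 - sum a_i), the stationary-mean relation of the difference
    equation.  p=0 degenerates to intercept = sample mean.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input series")
    if p < 0:
        raise ValueError("order must be >= 0")
    mean = float(x.mean())
    if p == 0:
        return ARModel(0, mean, np.zeros(0), float(x.var()))
    if x.size <= 10 * p:
        raise ValueError(f"need more than 10*p={10 * p} samples, got {x.size}")
    try:
        rho, sigma = yule_walker(x, order=p, method="mle", demean=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular autocovariance: {exc}") from exc
    intercept = mean * (1.0 - float(rho.sum()))
    return ARModel(p, intercept, rho, float(sigma**2))


def welch_psd(
    x: np.ndarray,
    fs: float,
    nperseg: int = 256,
    overlap: float = 0.5,
) -> PSDEstimate:
    """Welch power spectral density of a 1-D series.

    Hann-windowed segments with the given fractional overlap (default 50%),
    density scaling so the spectrum integrates to approximately the signal
    variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    if nperseg > x.size:
        raise ValueError(f"nperseg={nperseg} exceeds series length {x.size}")
    noverlap = int(round(nperseg * overlap))
    f, p = _signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density",
    )
    return PSDEstimate(frequencies=f, power=p, resolution=float(f[1] - f[0]))


def band_powers(
    x: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    nperseg: int = 256,
) -> np.ndarray:
    """Integrated Welch power in each band, in the dict's order."""
    bands = bands or CLASSICAL_BANDS
    nperseg = min(nperseg, np.asarray(x).size)
    psd = welch_psd(x, fs=fs, nperseg=nperseg)
    return np.array([psd.band_power(lo, hi) for lo, hi in bands.values()])


def extract_features(
    batch: SegmentBatch,
    fs: float,
    p: int = 6,
    bands: dict[str, tuple[float, float]] | None = None,
    use_ar: bool = True,
    use_psd: bool = True,
    nperseg: int = 256,
) -> list[FeatureVector]:
    """Per segment, concatenate per-channel AR coefficients and band powers.

    With K channels, order p and B bands the feature dimension is K*(p+B);
    either block can be switched off.
    """
    if not (use_ar or use_psd):
        raise ValueError("at least one of use_ar/use_psd must be set")
    bands = bands or CLASSICAL_BANDS
    out = []
    for seg, (subj, _task, cls) in zip(batch.segments, batch.labels):
        parts = []
        for ch in seg:
            if use_ar:
                parts.append(ar_coefficients(ch, p).coefficients)
            if use_psd:
                parts.append(band_powers(ch, fs=fs, bands=bands, nperseg=nperseg))
        out.append(FeatureVector(np.concatenate(parts), subject_id=subj, class_id=cls))
    return out


def feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack FeatureVectors into (X, subject_labels, class_labels)."""
    X = np.stack([f.values for f in features])
    return X, np.array([f.subject_id for f in features]), np.array([f.class_id for f in features])
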