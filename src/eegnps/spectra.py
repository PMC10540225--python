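"""Spectral quantitative EEG: epoching, average reference, log power spectra,
and GSF-corrected normative z-spectra.

The pipeline mirrors classic channel-space qEEG practice: fixed 2.56-s
artifact-free epochs, average reference, epoch-averaged periodograms on a
48-bin grid (0.78125--19.140625 Hz, step 1/2.56 Hz), natural-log transform,
and standardization against age-regression norms after removing a per-record
Global Scale Factor (GSF) -- the grand-mean log deviation from the normative
mean, i.e. the least-squares estimate of a common log-scale offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNELS_1020",
    "FREQ_GRID",
    "EPOCH_SECONDS",
    "EpochedEEG",
    "LogSpectra",
    "ZSpectra",
    "InsufficientEpochsError",
    "segment_epochs",
    "average_reference",
    "log_power_spectra",
    "NormativeSpectraModel",
    "fit_norms",
    "normative_z",
]

#: The 19-channel 10--20 montage used throughout.
CHANNELS_1020 = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "Cz", "C3", "C4",
    "T3", "T4", "T5", "T6", "Pz", "P3", "P4", "O1", "O2",
)

EPOCH_SECONDS = 2.56
FREQ_STEP = 1.0 / EPOCH_SECONDS  # 0.390625 Hz

#: 48 bin centers k * 0.390625 Hz for k = 2..49 (0.78125 .. 19.140625 Hz).
FREQ_GRID = np.arange(2, 50) * FREQ_STEP

VALID_RATES = (100, 200)


class InsufficientEpochsError(ValueError):
    """Raised when a record yields fewer artifact-free epochs than required."""

    def __init__(self, subject_id, n_found, n_required):
        self.subject_id = subject_id
        self.n_found = n_found
        self.n_required = n_required
        super().__init__(
            f"subject {subject_id!r}: only {n_found} epochs available, "
            f"minimum is {n_required}; record rejected"
        )


def _check_rate(rate):
    if rate not in VALID_RATES:
        raise ValueError(f"sampling rate must be one of {VALID_RATES}, got {rate}")


@dataclass
class EpochedEEG:
    """Clean fixed-length EEG epochs for one subject and wave.

    ``epochs`` has shape (n_epochs, n_channels, n_samples) in microvolts,
    with n_samples = round(rate * 2.56) in {256, 512}.
    """

    subject_id: object
    wave: str
    channel_labels: tuple
    rate: int
    epochs: np.ndarray

    def __post_init__(self):
        _check_rate(self.rate)
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, n_channels, n_samples)")
        n_exp = round(self.rate * EPOCH_SECONDS)
        if self.epochs.shape[2] != n_exp:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != round(rate*2.56) = {n_exp}"
            )
        labels = tuple(self.channel_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        unknown = set(labels) - set(CHANNELS_1020)
        if unknown:
            raise ValueError(f"channel labels not in the 10-20 montage: {sorted(unknown)}")
        if self.epochs.shape[1] != len(labels):
            raise ValueError("channel axis does not match channel_labels")
        self.channel_labels = labels

    @property
    def n_epochs(self):
        return self.epochs.shape[0]

    @property
    def n_channels(self):
        return self.epochs.shape[1]


@dataclass
class LogSpectra:
    """Natural-log epoch-averaged power per channel on the 48-bin grid."""

    subject_id: object
    wave: str
    channel_labels: tuple
    values: np.ndarray  # (n_channels, 48)
    freqs: np.ndarray = field(default_factory=lambda: FREQ_GRID.copy())

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channel_labels), len(FREQ_GRID)):
            raise ValueError("values must be (n_channels, 48)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log spectra contain non-finite values")


@dataclass
class ZSpectra:
    """GSF-corrected normative z log-power per channel x bin."""

    subject_id: object
    wave: str
    channel_labels: tuple
    gsf: float
    z: np.ndarray  # (n_channels, 48)


def segment_epochs(signal, rate, epoch_seconds=EPOCH_SECONDS, min_epochs=20,
                   subject_id=None, wave=None, channel_labels=None):
    """Cut a continuous multichannel record into non-overlapping epochs.

    ``signal`` is (n_channels, n_samples) or 1-D; the trailing remainder is
    discarded.  Fewer than ``min_epochs`` complete epochs raises
    :class:`InsufficientEpochsError` so the record can be flagged.
    """
    _check_rate(rate)
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n_per = round(rate * epoch_seconds)
    n_ep = x.shape[1] // n_per
    if n_ep < min_epochs:
        raise InsufficientEpochsError(subject_id, n_ep, min_epochs)
    trimmed = x[:, : n_ep * n_per]
    epochs = trimmed.reshape(x.shape[0], n_ep, n_per).transpose(1, 0, 2)
    if channel_labels is None:
        channel_labels = CHANNELS_1020[: x.shape[0]]
    return EpochedEEG(subject_id=subject_id, wave=wave,
                      channel_labels=channel_labels, rate=rate, epochs=epochs)


def average_reference(eeg):
    """Re-reference to the instantaneous channel mean (sums to zero per sample)."""
    if eeg.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    ref = eeg.epochs.mean(axis=1, keepdims=True)
    return EpochedEEG(subject_id=eeg.subject_id, wave=eeg.wave,
                      channel_labels=eeg.channel_labels, rate=eeg.rate,
                      epochs=eeg.epochs - ref)


def periodogram_bins(x, rate):
    """Rectangular-window periodogram of one epoch restricted to the 48-bin grid.

    Power at DFT bin k is |sum_t x_t e^{-2 pi i k t / N}|^2 / N.  The epoch
    length N = rate * 2.56 makes the DFT bin spacing exactly 1/2.56 Hz, so
    grid bins are DFT bins k = 2..49 with no interpolation.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    power = (X.real ** 2 + X.imag ** 2) / n
    return power[..., 2:50]


def log_power_spectra(eeg):
    """Epoch-averaged periodogram per channel, 48-bin grid, natural log."""
    power = periodogram_bins(eeg.epochs, eeg.rate)  # (n_ep, n_ch, 48)
    mean_power = power.mean(axis=0)
    if np.any(~np.isfinite(mean_power)) or np.any(mean_power <= 0):
        raise ValueError("zero or non-finite power encountered; cannot take log")
    return LogSpectra(subject_id=eeg.subject_id, wave=eeg.wave,
                      channel_labels=eeg.channel_labels,
                      values=np.log(mean_power))


class NormativeSpectraModel:
    """Age-regression norms for log spectra: per (channel, bin) a quadratic
    polynomial in ln(age) for the mean and a homoscedastic residual SD.

    scikit-learn style: ``fit(X, ages)`` with X of shape (n, n_channels, 48),
    then ``transform(X, ages)`` returns z arrays; :meth:`zscore` returns a
    full :class:`ZSpectra` (with GSF) for a single record.
    """

    def __init__(self, min_reference=30):
        self.min_reference = min_reference

    def get_params(self, deep=True):
        return {"min_reference": self.min_reference}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, ages, channel_labels=CHANNELS_1020):
        X = np.asarray(X, dtype=float)
        ages = np.asarray(ages, dtype=float)
        if X.ndim != 3 or X.shape[0] != ages.shape[0]:
            raise ValueError("X must be (n, n_channels, 48) aligned with ages")
        n = X.shape[0]
        if n < self.min_reference:
            raise ValueError(f"reference sample too small: {n} < {self.min_reference}")
        la = np.log(ages)
        D = np.column_stack([np.ones(n), la, la ** 2])
        if np.linalg.matrix_rank(D) < 3:
            raise ValueError("degenerate age spread: design matrix is rank-deficient")
        Y = X.reshape(n, -1)
        coef, _, _, _ = np.linalg.lstsq(D, Y, rcond=None)
        resid = Y - D @ coef
        dof = max(n - 3, 1)
        sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
        if np.any(sd <= 1e-12):
            raise ValueError("near-zero residual SD in normative fit")
        self.channel_labels_ = tuple(channel_labels)
        self.coef_ = coef.reshape(3, X.shape[1], X.shape[2])
        self.sigma_ = sd.reshape(X.shape[1], X.shape[2])
        self.age_range_ = (float(ages.min()), float(ages.max()))
        self.n_reference_ = n
        return self

    def predict_mean(self, age):
        """Normative mean log spectrum at a given age, shape (n_channels, 48)."""
        la = np.log(float(age))
        return self.coef_[0] + la * self.coef_[1] + la ** 2 * self.coef_[2]

    def transform(self, X, ages):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        gsf = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            zs = normative_z_values(X[i], self, ages[i])
            gsf[i], out[i] = zs
        return out, gsf

    def zscore(self, log_spectra, age):
        """GSF-corrected z-spectra for one :class:`LogSpectra` record."""
        gsf, z = normative_z_values(log_spectra.values, self, age)
        return ZSpectra(subject_id=log_spectra.subject_id, wave=log_spectra.wave,
                        channel_labels=log_spectra.channel_labels, gsf=gsf, z=z)


def normative_z_values(values, model, age):
    """gsf = mean(log s - mu(age)); z = (log s - gsf - mu) / sigma."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("NaN/inf in log spectra")
    lo, hi = model.age_range_
    if not (lo <= age <= hi):
        warnings.warn(
            f"age {age} outside normative range [{lo:.1f}, {hi:.1f}]; extrapolating",
            stacklevel=2,
        )
    mu = model.predict_mean(age)
    dev = values - mu
    gsf = float(dev.mean())
    z = (dev - gsf) / model.sigma_
    return gsf, z


def fit_norms(reference_spectra, ages):
    """Fit a :class:`NormativeSpectraModel` from a list of LogSpectra."""
    labels = reference_spectra[0].channel_labels
    X = np.stack([s.values for s in reference_spectra])
    return NormativeSpectraModel().fit(X, np.asarray(ages, float), channel_labels=labels)


def normative_z(log_spectra, model, age):
    """Functional wrapper over :meth:`NormativeSpectraModel.zscore`."""
    return model.zscore(log_spectra, age)
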