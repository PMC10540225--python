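"""Spectral pipeline: epoching, referencing, periodograms, norms, z-scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegnps.spectra import (FREQ_GRID, CHANNELS_1020, EpochedEEG,
                            InsufficientEpochsError, segment_epochs,
                            average_reference, log_power_spectra,
                            NormativeSpectraModel, normative_z_values)


def test_frequency_grid():
    assert len(FREQ_GRID) == 48
    assert FREQ_GRID[0] == pytest.approx(0.78125)
    assert FREQ_GRID[-1] == pytest.approx(19.140625)
    assert np.allclose(np.diff(FREQ_GRID), 1 / 2.56)


@pytest.mark.parametrize("seconds,rate,expected", [
    (61.44, 100, 24),   # typical one-minute record
    (2.56, 200, 1),     # exactly one epoch, no remainder
])
def test_segment_epoch_counts(seconds, rate, expected):
    sig = np.random.default_rng(0).standard_normal((2, int(seconds * rate)))
    eeg = segment_epochs(sig, rate, min_epochs=1)
    assert eeg.n_epochs == expected
    assert eeg.epochs.shape[2] == round(rate * 2.56)


def test_segment_rejects_short_record():
    sig = np.zeros((2, int(51.1 * 200)))   # floor(51.1/2.56) = 19 < 20
    with pytest.raises(InsufficientEpochsError) as exc:
        segment_epochs(sig, 200, subject_id="S1")
    assert exc.value.n_found == 19
    assert "S1" in str(exc.value)


def test_segment_rejects_bad_rate():
    with pytest.raises(ValueError):
        segment_epochs(np.zeros((1, 1000)), 128)


def _toy_eeg(rng, n_ch=3, n_ep=2, rate=100):
    x = rng.standard_normal((n_ep, n_ch, 256))
    return EpochedEEG("t", "childhood", CHANNELS_1020[:n_ch], rate, x)


def test_average_reference_properties(rng):
    eeg = _toy_eeg(rng)
    ref = average_reference(eeg)
    # channel sum is zero at every sample
    assert np.abs(ref.epochs.sum(axis=1)).max() < 1e-9 * np.abs(eeg.epochs).max()
    # common-mode rejection: adding a constant to all channels changes nothing
    shifted = EpochedEEG("t", "childhood", eeg.channel_labels, 100, eeg.epochs + 7.5)
    np.testing.assert_allclose(average_reference(shifted).epochs, ref.epochs)
    # idempotence
    np.testing.assert_allclose(average_reference(ref).epochs, ref.epochs)


def test_average_reference_two_balanced_channels():
    x = np.stack([np.ones((1, 256)), -np.ones((1, 256))], axis=1)
    eeg = EpochedEEG("t", "w", CHANNELS_1020[:2], 100, x)
    np.testing.assert_allclose(average_reference(eeg).epochs, x)


def test_average_reference_single_channel_error(rng):
    eeg = _toy_eeg(rng, n_ch=1)
    with pytest.raises(ValueError):
        average_reference(eeg)


def test_periodogram_matches_direct_dft(rng):
    """Epoch-averaged log power equals a naive DFT-sum oracle to 1e-8."""
    x = rng.standard_normal((1, 2, 256))
    eeg = EpochedEEG("t", "w", CHANNELS_1020[:2], 100, x)
    spec = log_power_spectra(eeg)
    n = 256
    t = np.arange(n)
    for ch in range(2):
        direct = []
        for k in range(2, 50):
            X = np.sum(x[0, ch] * np.exp(-2j * np.pi * k * t / n))
            direct.append(np.abs(X) ** 2 / n)
        np.testing.assert_allclose(np.exp(spec.values[ch]), direct, rtol=1e-8)


def test_sinusoid_concentrates_in_its_bin():
    rate, n = 100, 256
    t = np.arange(24 * n) / rate
    sig = np.sin(2 * np.pi * 10.15625 * t)   # exactly bin k=26 -> grid index 24
    eeg = segment_epochs(sig[None, :], rate, min_epochs=20,
                         channel_labels=("Cz",))
    spec = log_power_spectra(eeg)
    power = np.exp(spec.values[0])
    assert np.argmax(power) == 24
    assert power[24] / max(power[23], power[25]) > 100


def test_white_noise_log_spectrum_flat():
    """Mean max-min log range over realizations stays below 1 at 24 epochs."""
    rng = np.random.default_rng(99)
    ranges = []
    for _ in range(100):
        x = rng.standard_normal((24, 1, 512))
        eeg = EpochedEEG("t", "w", ("Cz",), 200, x)
        vals = log_power_spectra(eeg).values[0]
        ranges.append(vals.max() - vals.min())
    assert np.mean(ranges) < 1.0


def test_zero_signal_rejected():
    eeg = EpochedEEG("t", "w", ("Cz",), 100, np.zeros((20, 1, 256)))
    with pytest.raises(ValueError):
        log_power_spectra(eeg)


# -- norms -----------------------------------------------------------------

def _norm_reference(rng, n=120, n_ch=2, n_bins=48):
    """Log spectra generated exactly from a quadratic-in-ln(age) surface."""
    ages = rng.uniform(5, 51, n)
    la = np.log(ages)
    beta = rng.normal(size=(3, n_ch, n_bins))
    mu = beta[0] + la[:, None, None] * beta[1] + (la ** 2)[:, None, None] * beta[2]
    X = mu + rng.normal(0, 0.3, size=mu.shape)
    return X, ages, beta


def test_norm_coefficient_recovery(rng):
    X, ages, beta = _norm_reference(rng)
    model = NormativeSpectraModel().fit(X, ages)
    # closed-form least squares oracle for one cell
    la = np.log(ages)
    D = np.column_stack([np.ones(len(ages)), la, la ** 2])
    bhat, *_ = np.linalg.lstsq(D, X[:, 0, 0], rcond=None)
    np.testing.assert_allclose(model.coef_[:, 0, 0], bhat, rtol=1e-8)
    # recovery of the generative surface within 3 SE (SE via lstsq covariance)
    cov = np.linalg.inv(D.T @ D) * 0.3 ** 2
    se = np.sqrt(np.diag(cov))
    assert np.all(np.abs(model.coef_[:, 0, 0] - beta[:, 0, 0]) < 3 * se)
    assert np.all(model.sigma_ > 0)


def test_norm_constant_age_rejected(rng):
    X, ages, _ = _norm_reference(rng)
    with pytest.raises(ValueError):
        NormativeSpectraModel().fit(X, np.full(len(ages), 8.0))


def test_norm_small_reference_rejected(rng):
    X, ages, _ = _norm_reference(rng, n=10)
    with pytest.raises(ValueError):
        NormativeSpectraModel().fit(X, ages)


# -- z-scoring -------------------------------------------------------------

def _fitted_toy_model():
    m = NormativeSpectraModel()
    m.coef_ = np.zeros((3, 2, 3))
    m.coef_[0] = np.array([[1.0, 2.0, 3.0], [0.0, -1.0, 1.5]])
    m.sigma_ = np.array([[0.5, 1.0, 2.0], [1.0, 0.25, 0.5]])
    m.age_range_ = (5.0, 51.0)
    m.channel_labels_ = ("C3", "C4")
    return m


def test_z_zero_when_spectra_equal_norm_mean():
    m = _fitted_toy_model()
    mu = m.predict_mean(10.0)
    gsf, z = normative_z_values(mu, m, 10.0)
    assert gsf == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(z, 0.0, atol=1e-12)


def test_z_with_cell_varying_sigma_direct_arithmetic():
    """Toy oracle: spectra = mu + 2*sigma with varying sigma."""
    m = _fitted_toy_model()
    mu = m.predict_mean(10.0)
    vals = mu + 2 * m.sigma_
    gsf, z = normative_z_values(vals, m, 10.0)
    expected_gsf = (2 * m.sigma_).mean()
    assert gsf == pytest.approx(expected_gsf)
    np.testing.assert_allclose(z, (2 * m.sigma_ - expected_gsf) / m.sigma_)


@settings(max_examples=30, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=1e6))
def test_gsf_scale_invariance(k):
    """Multiplying power by k shifts GSF by ln k and leaves z unchanged."""
    m = _fitted_toy_model()
    rng = np.random.default_rng(7)
    vals = m.predict_mean(30.0) + rng.normal(0, 1, size=(2, 3))
    g0, z0 = normative_z_values(vals, m, 30.0)
    g1, z1 = normative_z_values(vals + np.log(k), m, 30.0)
    assert g1 - g0 == pytest.approx(np.log(k), rel=1e-9, abs=1e-9)
    np.testing.assert_allclose(z0, z1, atol=1e-9)


def test_z_population_calibration(rng):
    """z of the norm-generating population has mean ~0 and SD ~1 per cell."""
    n = 200
    ages = rng.uniform(5, 51, n)
    la = np.log(ages)
    mu = 1.0 + 0.5 * la[:, None, None] - 0.05 * (la ** 2)[:, None, None]
    X = np.broadcast_to(mu, (n, 2, 48)).copy()
    X += rng.normal(0, 0.4, size=X.shape)
    X += rng.normal(0, 0.1, size=(n, 1, 1))   # per-record scale offset (GSF truth)
    model = NormativeSpectraModel().fit(X, ages, channel_labels=("C3", "C4"))
    Z, gsf = model.transform(X, ages)
    assert np.abs(Z.mean(axis=0)).max() < 0.1
    sds = Z.std(axis=0, ddof=1)
    assert sds.min() > 0.85 and sds.max() < 1.15


def test_z_nan_rejected():
    m = _fitted_toy_model()
    bad = m.predict_mean(10.0)
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        normative_z_values(bad, m, 10.0)
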