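"""Synthetic two-wave, two-group EEG cohorts.

Emulates the data structure of a longitudinal nutrition cohort: a previously
malnourished group (PEM) and matched controls (CON) recorded in childhood
(5--11 years) and middle adulthood (45--51 years).  A latent "neurophysiological
abnormality" trait theta drives everything downstream:

* theta_{i,wave} = shift * 1[PEM] + age_slope * age + b_i + e_{i,wave},
  with b_i ~ N(0, subject_sd^2), e ~ N(0, wave_sd^2), and
  subject_sd^2 + wave_sd^2 = 1 so the trait has SD 1 in controls at fixed age.
* EEG channels are spatially correlated mixtures of one-over-f background,
  a band-limited alpha rhythm, and a theta-band component whose power scales
  with (1 + theta_gain * theta).
* Two evaluators score ordinal rating items generatively from a generalized
  partial credit model applied to theta perturbed by evaluator noise.
* Cognition subscales are generated from a trait negatively linked to adult
  theta.
* Wave-2 presence follows a logistic MCAR/MAR/MNAR dropout model with a
  configurable marginal retention rate.

All draws come from ``numpy.random.Generator`` streams derived from a single
seed, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .spectra import CHANNELS_1020, EPOCH_SECONDS, segment_epochs

__all__ = [
    "SimulationConfig",
    "WAVES",
    "DEFAULT_GTE_ITEMS",
    "DEFAULT_MOCA_ITEMS",
    "generate_cohort",
    "generate_eeg",
    "iter_eeg",
    "generate_ratings",
    "apply_missingness",
    "gpcm_draw",
]

WAVES = ("childhood", "adulthood")

# Ordinal rating item bank: name -> (discrimination, step thresholds, waves).
# Category ranges follow the standard grand-total EEG item grading
# (background frequency 0-2, diffuse slow 0-3, reactivity 0-2, focal 0-5,
# paroxysmal 0-3, sharp waves 0-2).  Reactivity requires comparing resting
# conditions and is scored in adulthood only.  High upper thresholds make the
# top sharp-wave / paroxysmal categories rare, as in clinical practice.
DEFAULT_GTE_ITEMS = {
    "Background frequency": {"a": 0.25, "b": (0.8, 2.0), "waves": WAVES},
    "Diffuse slow activity": {"a": 1.5, "b": (0.0, 1.2, 2.2), "waves": WAVES},
    "Reactivity": {"a": 1.2, "b": (1.0, 2.2), "waves": ("adulthood",)},
    "Focal abnormality": {"a": 3.0, "b": (0.2, 1.0, 1.8, 2.6, 3.2), "waves": WAVES},
    "Paroxysmal activity": {"a": 1.8, "b": (1.0, 3.5, 4.2), "waves": WAVES},
    "Sharp waves": {"a": 1.3, "b": (1.2, 3.6), "waves": WAVES},
}

# Cognition subscales scored 0..max as on the MoCA (max total 30); most
# respondents score near ceiling, hence mostly negative thresholds.
DEFAULT_MOCA_ITEMS = {
    "visuospatial": {"a": 1.5, "b": (-2.6, -2.0, -1.4, -0.8, 0.0)},
    "naming": {"a": 1.2, "b": (-3.0, -2.2, -1.2)},
    "attention": {"a": 2.2, "b": (-2.8, -2.2, -1.6, -1.0, -0.4, 0.2)},
    "language": {"a": 2.5, "b": (-2.4, -1.4, -0.2)},
    "abstraction": {"a": 1.8, "b": (-1.8, -0.4)},
    "memory": {"a": 1.5, "b": (-2.2, -1.5, -0.8, -0.1, 0.6)},
    "orientation": {"a": 1.0, "b": (-4.0, -3.4, -2.8, -2.2, -1.6, -1.0)},
}

MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass
class SimulationConfig:
    """Free parameters of the cohort generator (one seed drives everything)."""

    n_per_group: int = 65
    group_theta_shift: float = 0.7
    age_slope: float = 0.01
    subject_sd: float = math.sqrt(0.7)
    wave_sd: float = math.sqrt(0.3)
    evaluator_noise_sd: float = 0.3
    n_evaluators: int = 2
    # demographics
    male_fraction: float = 0.59
    left_handed_fraction: float = 0.05
    pem_ecology_shift: float = -1.2
    # EEG signal model
    rate_by_wave: dict = field(default_factory=lambda: {"childhood": 100, "adulthood": 200})
    n_epochs: int = 24
    alpha_center_hz: float = 10.0
    alpha_width_hz: float = 1.0
    alpha_amplitude: float = 2.0
    one_over_f_exponent: float = 1.0
    background_amplitude: float = 1.0
    theta_center_hz: float = 5.5
    theta_width_hz: float = 1.5
    theta_amplitude: float = 1.0
    theta_gain: float = 0.3
    channel_correlation: float = 0.6
    subject_scale_sd: float = 0.1  # per-record log amplitude offset (the GSF truth)
    # rating / cognition generators
    gte_items: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GTE_ITEMS.items()})
    moca_items: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOCA_ITEMS.items()})
    moca_link: float = 0.5
    # missingness
    mechanism: str = "MAR"
    gamma: float = 0.0
    retention: float = 0.65
    miss_group_coef: float = -0.3
    miss_baseline_coef: float = -0.3
    seed: int = 0

    def validate(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("subject_sd", "wave_sd", "evaluator_noise_sd", "subject_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must be in (0, 1]")
        for wave, rate in self.rate_by_wave.items():
            if rate not in (100, 200):
                raise ValueError(f"sampling rate for {wave} must be 100 or 200")
        if self.n_epochs < 20:
            raise ValueError("n_epochs must be >= 20")
        return self

    def replace(self, **kw):
        return replace(self, **kw)


def _rng(config, stream):
    """Independent generator for a named stage, deterministic in config.seed."""
    streams = {"cohort": 0, "eeg": 1, "ratings": 2, "missingness": 3, "moca": 4}
    return np.random.default_rng([int(config.seed), streams[stream]])


def generate_cohort(config):
    """Balanced PEM/CON cohort with matched pairs and the latent trait.

    Pairs share age, sex and handedness (the matching design).  Ecology is
    standardized to mean 0, SD 1 over the generated cohort after applying the
    group disadvantage shift.
    """
    config.validate()
    rng = _rng(config, "cohort")
    n = config.n_per_group
    age_child = rng.uniform(5.0, 11.0, size=n)
    sex = np.where(rng.uniform(size=n) < config.male_fraction, "M", "F")
    hand = np.where(rng.uniform(size=n) < config.left_handed_fraction, "L", "R")

    rows = []
    for g_idx, group in enumerate(("CON", "PEM")):
        for i in range(n):
            rows.append({
                "subject_id": f"S{g_idx * n + i:04d}",
                "group": group,
                "sex": sex[i],
                "handedness": hand[i],
                "age_childhood": age_child[i],
                "age_adulthood": age_child[i] + 40.0,
            })
    df = pd.DataFrame(rows)

    ecology = rng.normal(size=2 * n)
    ecology = ecology + np.where(df["group"] == "PEM", config.pem_ecology_shift, 0.0)
    df["ecology"] = (ecology - ecology.mean()) / ecology.std(ddof=0)

    b = rng.normal(0.0, config.subject_sd, size=2 * n)
    is_pem = (df["group"] == "PEM").to_numpy().astype(float)
    for wave in WAVES:
        e = rng.normal(0.0, config.wave_sd, size=2 * n)
        df[f"theta_{wave}"] = (
            config.group_theta_shift * is_pem
            + config.age_slope * df[f"age_{wave}"].to_numpy()
            + b + e
        )
    df["present_childhood"] = True
    df["present_adulthood"] = True
    return df


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _colored_signal(rng, config, theta, rate, n_total, n_channels):
    """Spatially correlated colored-noise mixture for one record."""
    freqs = np.fft.rfftfreq(n_total, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    amp[pos] = config.background_amplitude * freqs[pos] ** (-config.one_over_f_exponent / 2.0)
    amp += config.alpha_amplitude * np.exp(
        -((freqs - config.alpha_center_hz) ** 2) / (2 * config.alpha_width_hz ** 2))
    theta_scale = math.sqrt(max(1.0 + config.theta_gain * theta, 0.05))
    amp += config.theta_amplitude * theta_scale * np.exp(
        -((freqs - config.theta_center_hz) ** 2) / (2 * config.theta_width_hz ** 2))

    rho = config.channel_correlation
    common = rng.standard_normal(n_total)
    own = rng.standard_normal((n_channels, n_total))
    white = math.sqrt(rho) * common[None, :] + math.sqrt(1.0 - rho) * own
    spectrum = np.fft.rfft(white, axis=1) * amp[None, :]
    return np.fft.irfft(spectrum, n=n_total, axis=1)


def iter_eeg(cohort, config, waves=WAVES):
    """Yield :class:`EpochedEEG` per subject x wave (memory-friendly).

    Child generator streams are spawned per record from the master seed, so
    the EEG of one subject does not depend on how many others are generated
    before it.
    """
    config.validate()
    root = np.random.SeedSequence([int(config.seed), 1])
    n_samples = {w: round(config.rate_by_wave[w] * EPOCH_SECONDS) for w in waves}
    for pos, row in enumerate(cohort.itertuples(index=False)):
        for w_idx, wave in enumerate(waves):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(1, pos, w_idx))
            rng = np.random.default_rng(child)
            rate = config.rate_by_wave[wave]
            n_total = config.n_epochs * n_samples[wave]
            theta = getattr(row, f"theta_{wave}")
            sig = _colored_signal(rng, config, theta, rate, n_total, len(CHANNELS_1020))
            scale = 10.0 * math.exp(rng.normal(0.0, config.subject_scale_sd))
            yield segment_epochs(scale * sig, rate, min_epochs=20,
                                 subject_id=row.subject_id, wave=wave,
                                 channel_labels=CHANNELS_1020)


def generate_eeg(cohort, config, waves=WAVES):
    """Materialized list of :class:`EpochedEEG`; see :func:`iter_eeg`."""
    return list(iter_eeg(cohort, config, waves=waves))


# ---------------------------------------------------------------------------
# Ratings and cognition
# ---------------------------------------------------------------------------

def _gpcm_cdf_draw(a, b, theta, u):
    """Inverse-CDF draw from the generalized partial credit model.

    Sharing the uniform ``u`` across evaluators makes evaluator differences
    come only from their trait perturbation (identical tables at zero noise).
    """
    b = np.asarray(b, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(a * (theta - b))])
    cum -= cum.max()
    p = np.exp(cum)
    p /= p.sum()
    return int(np.searchsorted(np.cumsum(p), u, side="right").clip(0, len(b)))


def gpcm_draw(a, b, theta, rng):
    """Single random GPCM response (convenience for tests)."""
    return _gpcm_cdf_draw(a, b, theta, rng.uniform())


def generate_ratings(cohort, config):
    """Ordinal GTE-style responses per subject x wave x evaluator, plus a
    cognition subscale table from the adult wave.

    Returns ``(gte_long, moca_wide)`` DataFrames.  Childhood rows omit the
    reactivity item.  Responses are guarded to lie within each item's range.
    """
    config.validate()
    for name, item in config.gte_items.items():
        if "a" not in item or "b" not in item or len(item["b"]) < 1:
            raise ValueError(f"incomplete item parameters for {name!r}")
    rng = _rng(config, "ratings")
    n = len(cohort)
    rows = []
    for wave in WAVES:
        theta = cohort[f"theta_{wave}"].to_numpy()
        items = {k: v for k, v in config.gte_items.items()
                 if wave in v.get("waves", WAVES)}
        # shared uniforms: one per subject x item, common to all evaluators
        u = {name: rng.uniform(size=n) for name in items}
        eps = rng.normal(0.0, config.evaluator_noise_sd,
                         size=(config.n_evaluators, n))
        for r in range(config.n_evaluators):
            theta_r = theta + eps[r]
            for name, item in items.items():
                k_max = len(item["b"])
                for i in range(n):
                    resp = _gpcm_cdf_draw(item["a"], item["b"], theta_r[i], u[name][i])
                    if not (0 <= resp <= k_max):  # pragma: no cover - generator guard
                        raise RuntimeError(f"response out of range for item {name!r}")
                    rows.append((cohort["subject_id"].iat[i], wave, r + 1, name, resp))
    gte = pd.DataFrame(rows, columns=["subject_id", "wave", "evaluator", "item", "response"])

    # cognition trait: negatively linked to adult abnormality
    rng_m = _rng(config, "moca")
    link = config.moca_link
    theta_cog = (-link * cohort["theta_adulthood"].to_numpy()
                 + math.sqrt(max(1.0 - link ** 2, 0.0)) * rng_m.standard_normal(n))
    moca = {"subject_id": cohort["subject_id"].to_numpy()}
    for name, item in config.moca_items.items():
        u = rng_m.uniform(size=n)
        moca[name] = [
            _gpcm_cdf_draw(item["a"], item["b"], theta_cog[i], u[i]) for i in range(n)
        ]
    moca = pd.DataFrame(moca)
    moca["total"] = moca.drop(columns="subject_id").sum(axis=1)
    return gte, moca


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def apply_missingness(cohort, mechanism=None, gamma=None, config=None,
                      retention=None, seed=None):
    """Draw wave-2 presence from a logistic dropout model.

    MCAR: intercept only.  MAR: + group + wave-1 trait.  MNAR: MAR terms +
    gamma * wave-2 trait.  The intercept is solved so the marginal retention
    matches ``retention``; the per-subject uniforms are drawn before the
    mechanism branch, so MNAR with gamma = 0 reproduces MAR exactly under the
    same seed.
    """
    if config is None:
        config = SimulationConfig()
    mechanism = config.mechanism if mechanism is None else mechanism
    gamma = config.gamma if gamma is None else gamma
    retention = config.retention if retention is None else retention
    if mechanism not in MECHANISMS:
        raise ValueError(f"mechanism must be one of {MECHANISMS}, got {mechanism!r}")
    if not (0 < retention <= 1):
        raise ValueError("retention must be in (0, 1]")

    rng = _rng(config, "missingness") if seed is None else np.random.default_rng(seed)
    u = rng.uniform(size=len(cohort))

    lin = np.zeros(len(cohort))
    if mechanism in ("MAR", "MNAR"):
        lin = (config.miss_group_coef * (cohort["group"] == "PEM").to_numpy(float)
               + config.miss_baseline_coef * cohort["theta_childhood"].to_numpy())
    if mechanism == "MNAR":
        lin = lin + gamma * cohort["theta_adulthood"].to_numpy()

    if retention >= 1.0:
        present = np.ones(len(cohort), bool)
    else:
        alpha = brentq(lambda a: expit(a + lin).mean() - retention, -40.0, 40.0)
        present = u < expit(alpha + lin)

    out = cohort.copy()
    out["present_adulthood"] = present
    return out
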