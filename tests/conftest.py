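import numpy as np
import pandas as pd
import pytest

from eegnps.simulate import SimulationConfig, gpcm_draw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimulationConfig(n_per_group=30, seed=42)


def simulate_gpcm_responses(true_items, n, rng):
    """Wide response matrix from known GPCM truth (shared test helper)."""
    theta = rng.standard_normal(n)
    X = np.array([[gpcm_draw(a, b, th, rng) for a, b in true_items]
                  for th in theta], dtype=float)
    return X, theta


def simulate_lme_cohort(rng, n_subjects=60, group_effect=-0.7, age_slope=0.01,
                        interaction=0.0, subject_sd=0.8, resid_sd=0.5,
                        n_evaluators=1, dropout=0.0):
    """Long-format univariate mixed-model data with known generative truth."""
    rows = []
    for i in range(n_subjects):
        g = "PEM" if i % 2 else "CON"
        b = rng.normal(0, subject_sd)
        sex = "M" if rng.uniform() < 0.5 else "F"
        eco = rng.normal()
        for wave, age in (("childhood", rng.uniform(5, 11)),
                          ("adulthood", rng.uniform(45, 51))):
            for ev in range(1, n_evaluators + 1):
                y = (group_effect * (g == "PEM") + age_slope * age
                     + interaction * age * (g == "PEM") + b
                     + rng.normal(0, resid_sd))
                rows.append(dict(subject_id=i, wave=wave, evaluator=ev,
                                 sqnps=y, group=g, age=age, sex=sex,
                                 ecology=eco))
    df = pd.DataFrame(rows)
    if dropout > 0:
        subjects = df["subject_id"].unique()
        dropped = subjects[rng.uniform(size=len(subjects)) < dropout]
        df.loc[df["subject_id"].isin(dropped) & (df["wave"] == "adulthood"),
               "sqnps"] = np.nan
    return df


def simulate_mlme_data(rng, n_subjects=30, qnps_group=0.6, sqnps_group=0.0,
                       sqnps_null=True, psi=((0.5, 0.2), (0.2, 0.5)),
                       resid=(0.6, 0.5)):
    """Stacked two-modality long data; sqnps can be pure noise (null)."""
    rows = []
    for i in range(n_subjects):
        g = "PEM" if i % 2 else "CON"
        b = rng.multivariate_normal([0, 0], np.asarray(psi))
        sex = "M" if rng.uniform() < 0.5 else "F"
        eco = rng.normal()
        for wave, age in (("childhood", rng.uniform(5, 11)),
                          ("adulthood", rng.uniform(45, 51))):
            yq = qnps_group * (g == "PEM") + 0.01 * age + b[0] + rng.normal(0, resid[0])
            ys = b[1] + rng.normal(0, resid[1])
            if not sqnps_null:
                ys += sqnps_group * (g == "PEM") + 0.01 * age
            for mod, y in (("qnps", yq), ("sqnps", ys)):
                rows.append(dict(subject_id=i, wave=wave, modality=mod, y=y,
                                 group=g, age=age, sex=sex, ecology=eco))
    return pd.DataFrame(rows)
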