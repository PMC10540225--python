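"""Synthetic cohort generator: determinism, planted effects, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegnps.simulate import (SimulationConfig, generate_cohort, generate_eeg,
                             generate_ratings, apply_missingness, iter_eeg)
from eegnps.spectra import FREQ_GRID, average_reference, log_power_spectra


def test_seed_determinism_bit_identical():
    cfg = SimulationConfig(n_per_group=50, seed=1)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    ga, ma = generate_ratings(a, cfg)
    gb, mb = generate_ratings(b, cfg)
    pd.testing.assert_frame_equal(ga, gb)
    pd.testing.assert_frame_equal(ma, mb)
    pa = apply_missingness(a, config=cfg)
    pb = apply_missingness(b, config=cfg)
    pd.testing.assert_frame_equal(pa, pb)


def test_cohort_invariants():
    cfg = SimulationConfig(n_per_group=120, seed=2)
    c = generate_cohort(cfg)
    assert (c.groupby("group").size() == 120).all()
    assert c["age_childhood"].between(5, 11).all()
    assert c["age_adulthood"].between(45, 51).all()
    assert abs(c["ecology"].mean()) < 0.1
    assert abs(c["ecology"].std() - 1) < 0.1
    assert c["present_childhood"].all()
    # matched pairs: same marginal sex/handedness per group
    assert (c[c.group == "PEM"]["sex"].values == c[c.group == "CON"]["sex"].values).all()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        generate_cohort(SimulationConfig(n_per_group=1))
    with pytest.raises(ValueError):
        SimulationConfig(mechanism="WRONG").validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_epochs=10).validate()


def test_null_shift_group_difference_small():
    """With no planted effect, group means differ by < 3 SE."""
    cfg = SimulationConfig(n_per_group=100, group_theta_shift=0.0, seed=3)
    c = generate_cohort(cfg)
    t, p = stats.ttest_ind(c.loc[c.group == "PEM", "theta_childhood"],
                           c.loc[c.group == "CON", "theta_childhood"])
    assert abs(t) < 3


def test_null_calibration_downstream_t():
    """Group t-test rejects at the nominal 5% rate under the null."""
    rej = 0
    n_sims = 500
    for seed in range(n_sims):
        cfg = SimulationConfig(n_per_group=30, group_theta_shift=0.0, seed=seed)
        c = generate_cohort(cfg)
        _, p = stats.ttest_ind(c.loc[c.group == "PEM", "theta_childhood"],
                               c.loc[c.group == "CON", "theta_childhood"])
        rej += p < 0.05
    assert 0.03 <= rej / n_sims <= 0.07


def test_planted_shift_recovered():
    """Monte-Carlo mean of the group difference matches the planted shift."""
    diffs = []
    for seed in range(20):
        cfg = SimulationConfig(n_per_group=200, group_theta_shift=1.0, seed=seed)
        c = generate_cohort(cfg)
        diffs.append(c.loc[c.group == "PEM", "theta_childhood"].mean()
                     - c.loc[c.group == "CON", "theta_childhood"].mean())
    assert 0.8 <= np.mean(diffs) <= 1.2


# -- EEG -------------------------------------------------------------------

def test_eeg_epoch_shape_and_rates():
    cfg = SimulationConfig(n_per_group=2, seed=4, n_epochs=23)
    c = generate_cohort(cfg)
    eegs = generate_eeg(c.head(1), cfg)
    by_wave = {e.wave: e for e in eegs}
    assert by_wave["childhood"].epochs.shape == (23, 19, 256)
    assert by_wave["adulthood"].epochs.shape == (23, 19, 512)


def test_eeg_alpha_peak_location():
    """Averaged periodogram peaks within 1 Hz of the configured alpha center."""
    cfg = SimulationConfig(n_per_group=2, seed=5, alpha_center_hz=10.0)
    c = generate_cohort(cfg)
    for eeg in iter_eeg(c.head(2), cfg, waves=("adulthood",)):
        spec = log_power_spectra(average_reference(eeg))
        band = (FREQ_GRID >= 6) & (FREQ_GRID <= 14)
        peak = FREQ_GRID[band][np.argmax(spec.values.mean(axis=0)[band])]
        assert 9.0 <= peak <= 11.0


def test_eeg_theta_gain_null():
    """theta_gain = 0 leaves no group difference in theta-band log power."""
    cfg = SimulationConfig(n_per_group=60, seed=6, theta_gain=0.0)
    c = generate_cohort(cfg)
    band = (FREQ_GRID >= 4) & (FREQ_GRID <= 7.5)
    vals = {}
    for eeg in iter_eeg(c, cfg, waves=("childhood",)):
        spec = log_power_spectra(eeg)
        vals[eeg.subject_id] = spec.values[:, band].mean()
    c = c.set_index("subject_id")
    a = [v for s, v in vals.items() if c.loc[s, "group"] == "PEM"]
    b = [v for s, v in vals.items() if c.loc[s, "group"] == "CON"]
    t, _ = stats.ttest_ind(a, b)
    assert abs(t) < 3


def test_eeg_rejects_bad_rate():
    cfg = SimulationConfig(n_per_group=2, seed=7,
                           rate_by_wave={"childhood": 100, "adulthood": 200})
    cfg.rate_by_wave["childhood"] = 128
    c_ok = generate_cohort(SimulationConfig(n_per_group=2, seed=7))
    with pytest.raises(ValueError):
        generate_eeg(c_ok, cfg)


# -- ratings ---------------------------------------------------------------

def test_evaluator_noise_zero_identical_tables():
    cfg = SimulationConfig(n_per_group=20, seed=8, evaluator_noise_sd=0.0)
    c = generate_cohort(cfg)
    gte, _ = generate_ratings(c, cfg)
    wide = gte.pivot_table(index=["subject_id", "wave", "item"],
                           columns="evaluator", values="response")
    assert (wide[1] == wide[2]).all()


def test_rating_ranges_and_reactivity():
    cfg = SimulationConfig(n_per_group=40, seed=9, group_theta_shift=2.0)
    c = generate_cohort(cfg)
    gte, moca = generate_ratings(c, cfg)
    max_cat = {name: len(item["b"]) for name, item in cfg.gte_items.items()}
    for name, grp in gte.groupby("item"):
        assert grp["response"].between(0, max_cat[name]).all()
    assert max_cat["Focal abnormality"] == 5
    child = gte[gte["wave"] == "childhood"]
    assert "Reactivity" not in set(child["item"])
    moca_max = {name: len(item["b"]) for name, item in cfg.moca_items.items()}
    for name, m in moca_max.items():
        assert moca[name].between(0, m).all()


def test_gte_group_difference_monotone_in_shift():
    """Larger planted shifts give larger PEM-CON gaps in total score."""
    gaps = []
    for shift in (0.0, 0.5, 1.0, 2.0):
        per_seed = []
        for seed in range(8):
            cfg = SimulationConfig(n_per_group=40, seed=seed,
                                   group_theta_shift=shift)
            c = generate_cohort(cfg)
            gte, _ = generate_ratings(c, cfg)
            tot = gte.groupby("subject_id")["response"].sum()
            grp = c.set_index("subject_id")["group"]
            per_seed.append(tot[grp == "PEM"].mean() - tot[grp == "CON"].mean())
        gaps.append(np.mean(per_seed))
    assert gaps == sorted(gaps)
    assert gaps[-1] > gaps[0] + 1


def test_missing_item_parameters_rejected():
    cfg = SimulationConfig(n_per_group=4, seed=1)
    cfg.gte_items["Sharp waves"] = {"a": 1.0, "b": (), "waves": ("childhood",)}
    c = generate_cohort(SimulationConfig(n_per_group=4, seed=1))
    with pytest.raises(ValueError):
        generate_ratings(c, cfg)


# -- missingness -----------------------------------------------------------

def test_retention_one_keeps_everyone():
    cfg = SimulationConfig(n_per_group=30, seed=10)
    c = generate_cohort(cfg)
    out = apply_missingness(c, mechanism="MCAR", retention=1.0, config=cfg)
    assert out["present_adulthood"].all()


def test_mnar_gamma_zero_equals_mar():
    cfg = SimulationConfig(n_per_group=50, seed=11)
    c = generate_cohort(cfg)
    mar = apply_missingness(c, mechanism="MAR", config=cfg)
    mnar0 = apply_missingness(c, mechanism="MNAR", gamma=0.0, config=cfg)
    assert (mar["present_adulthood"] == mnar0["present_adulthood"]).all()


def test_marginal_retention_close_to_target():
    cfg = SimulationConfig(n_per_group=300, seed=12)
    c = generate_cohort(cfg)
    for mech, gamma in (("MCAR", 0.0), ("MAR", 0.0), ("MNAR", 2.0)):
        out = apply_missingness(c, mechanism=mech, gamma=gamma,
                                retention=0.65, config=cfg)
        assert abs(out["present_adulthood"].mean() - 0.65) < 0.06


def test_mnar_selects_on_outcome():
    """Under MNAR the retained and dropped wave-2 traits differ."""
    n_pos = 0
    for seed in range(100):
        cfg = SimulationConfig(n_per_group=40, seed=seed)
        c = generate_cohort(cfg)
        out = apply_missingness(c, mechanism="MNAR", gamma=2.0,
                                retention=0.6, config=cfg)
        kept = out.loc[out.present_adulthood, "theta_adulthood"].mean()
        dropped = out.loc[~out.present_adulthood, "theta_adulthood"].mean()
        n_pos += (kept - dropped) > 0
    assert n_pos >= 95


def test_missingness_errors():
    cfg = SimulationConfig(n_per_group=5, seed=13)
    c = generate_cohort(cfg)
    with pytest.raises(ValueError):
        apply_missingness(c, mechanism="BAD", config=cfg)
    with pytest.raises(ValueError):
        apply_missingness(c, retention=0.0, config=cfg)
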