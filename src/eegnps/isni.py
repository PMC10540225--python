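"""Index of local sensitivity to non-ignorability (ISNI) for the univariate
mixed model with wave-2 dropout.

The selection model is logistic in observed covariates (intercept, group,
wave-1 outcome) plus gamma times the possibly unobserved wave-2 outcome
(the average of a subject's missing wave-2 rows).  The index is the
first-order Taylor displacement of each fixed-effect ML estimate in gamma at
gamma = 0:

    ISNI = M^{-1} sum_{dropped i} (1 - h_i) d_i,
    M   = sum_i X_oi' V_oi^{-1} X_oi,
    d_i = xbar_mi - X_oi' V_oi^{-1} V_omi 1/m_i,

where h_i is the fitted probability of dropout given observed covariates,
V blocks come from the ignorable fit's variance components (random subject
intercept + residual), and xbar_mi is the mean design row of the missing
observations.  Only subjects with missing rows contribute: with complete
data every index is exactly zero.

The standardized statistic c = |sigma * SE / ISNI| (sigma = residual SD of
the ignorable fit) is invariant to rescaling the outcome; the conventional
reading is that c >= 1 marks an estimate robust to plausible non-ignorable
dropout.

:func:`profile_estimate_at_gamma` maximizes the actual joint selection-model
likelihood at a given gamma (variance components held at their ignorable ML
values) and exists to verify the index by finite differences; it is not an
analysis path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from .longitudinal import build_design

__all__ = ["ISNIResult", "compute_isni", "profile_estimate_at_gamma"]


@dataclass
class ISNIResult:
    table: pd.DataFrame      # per fixed effect: estimate, se, isni, c, robust
    sigma: float             # residual SD of the ignorable fit
    n_dropped: int
    missing_model: dict      # logistic dropout-model coefficients


def _subject_blocks(data, fit, outcome, subject_col, wave_col, wave2):
    """Per-subject design/covariance partition into observed and missing rows."""
    X = build_design(data)
    sig_b = fit.vc.get("subject", 0.0)
    sig_e = fit.vc["residual"]
    blocks = []
    for sid, sub in data.groupby(subject_col, sort=True):
        Xi = X.loc[sub.index].to_numpy(float)
        yi = sub[outcome].to_numpy(float)
        obs = ~np.isnan(yi)
        k = len(sub)
        V = sig_b * np.ones((k, k)) + sig_e * np.eye(k)
        blocks.append({
            "subject": sid, "X": Xi, "y": yi, "obs": obs, "V": V,
            "wave2": (sub[wave_col] == wave2).to_numpy(),
        })
    return blocks, list(X.columns)


def _dropout_model(data, outcome, subject_col, wave_col, wave2,
                   covariates=("group", "baseline")):
    """Logistic model of wave-2 dropout on an intercept plus the requested
    observed covariates ('group' and/or the wave-1 outcome 'baseline')."""
    per = []
    for sid, sub in data.groupby(subject_col, sort=True):
        w2 = sub[sub[wave_col] == wave2]
        w1 = sub[sub[wave_col] != wave2]
        dropped = bool(w2[outcome].isna().all()) if len(w2) else False
        per.append({
            "subject": sid,
            "dropped": dropped,
            "group": float((sub["group"] == "PEM").any()),
            "baseline": float(w1[outcome].mean()) if len(w1) else 0.0,
        })
    per = pd.DataFrame(per).set_index("subject")
    W = sm.add_constant(per[list(covariates)]) if covariates else \
        pd.DataFrame({"const": np.ones(len(per))}, index=per.index)
    if per["dropped"].nunique() < 2:
        # no (or universal) dropout: probabilities are the observed rate
        rate = float(per["dropped"].mean())
        per["h"] = rate
        return per, {"const": np.nan, "group": np.nan, "baseline": np.nan}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logit = sm.Logit(per["dropped"].astype(float), W).fit(disp=0)
        per["h"] = logit.predict(W)
        coefs = dict(zip(W.columns, logit.params))
    except Exception:  # separation etc.
        warnings.warn("dropout logistic model failed; using marginal rate")
        per["h"] = float(per["dropped"].mean())
        coefs = {c: np.nan for c in W.columns}
    return per, coefs


def compute_isni(fit, data, outcome="sqnps", subject_col="subject_id",
                 wave_col="wave", wave2="adulthood", c_threshold=1.0,
                 missing_covariates=("group", "baseline")):
    """ISNI and the c statistic for every fixed effect of an ignorable LME fit.

    ``data`` must contain the design covariates for *all* rows, including
    wave-2 rows whose outcome is missing (NaN) -- those rows carry the
    covariate profile of the unobserved measurements.
    """
    blocks, names = _subject_blocks(data, fit, outcome, subject_col, wave_col, wave2)
    per, coefs = _dropout_model(data, outcome, subject_col, wave_col, wave2,
                                covariates=missing_covariates)

    p = len(names)
    M = np.zeros((p, p))
    H = np.zeros(p)
    n_dropped = 0
    for blk in blocks:
        obs = blk["obs"]
        Xo = blk["X"][obs]
        Vo = blk["V"][np.ix_(obs, obs)]
        if obs.any():
            Vo_inv = np.linalg.inv(Vo)
            M += Xo.T @ Vo_inv @ Xo
        mis = ~obs
        if not mis.any():
            continue
        n_dropped += 1
        Xm = blk["X"][mis]
        xbar = Xm.mean(axis=0)
        if obs.any():
            Vom = blk["V"][np.ix_(obs, mis)]
            d = xbar - Xo.T @ Vo_inv @ Vom.mean(axis=1)
        else:
            d = xbar
        h = float(per.loc[blk["subject"], "h"])
        H += (1.0 - h) * d

    est = fit.fe_table["estimate"].reindex(names).to_numpy()
    se = fit.fe_table["se"].reindex(names).to_numpy()
    sigma = fit.resid_sd
    if n_dropped == 0:
        isni = np.zeros(p)
    else:
        isni = np.linalg.solve(M, H)
    with np.errstate(divide="ignore"):
        c = np.where(isni == 0.0, np.inf, np.abs(sigma * se / isni))
    table = pd.DataFrame({
        "estimate": est, "se": se, "isni": isni, "c": c,
        "robust": c >= c_threshold,
    }, index=pd.Index(names, name="term"))
    return ISNIResult(table=table, sigma=sigma, n_dropped=n_dropped,
                      missing_model=coefs)


def profile_estimate_at_gamma(fit, data, gamma, outcome="sqnps",
                              subject_col="subject_id", wave_col="wave",
                              wave2="adulthood", n_quad=40,
                              missing_covariates=("group", "baseline")):
    """Fixed effects maximizing the joint selection-model likelihood at gamma.

    Variance components and the dropout-model coefficients are held at their
    gamma = 0 ML values, matching the first-order expansion the index
    linearizes.  Used as the finite-difference verification oracle.
    """
    blocks, names = _subject_blocks(data, fit, outcome, subject_col, wave_col, wave2)
    per, _ = _dropout_model(data, outcome, subject_col, wave_col, wave2,
                            covariates=missing_covariates)
    u_lin = np.log(per["h"] / (1.0 - per["h"])).replace([np.inf, -np.inf], 0.0)

    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    pre = []
    for blk in blocks:
        obs = blk["obs"]
        mis = ~obs
        Xo, yo = blk["X"][obs], blk["y"][obs]
        Vo_inv = np.linalg.inv(blk["V"][np.ix_(obs, obs)]) if obs.any() else None
        item = {"Xo": Xo, "yo": yo, "Vo_inv": Vo_inv, "mis": None}
        if mis.any():
            m = int(mis.sum())
            Xm = blk["X"][mis]
            ones = np.ones(m) / m
            Vmm = blk["V"][np.ix_(mis, mis)]
            if obs.any():
                Vom = blk["V"][np.ix_(obs, mis)]
                w = Vo_inv @ (Vom @ ones)                  # weights on observed resid
                s2 = ones @ (Vmm - Vom.T @ Vo_inv @ Vom) @ ones
            else:
                w = np.zeros(0)
                s2 = ones @ Vmm @ ones
            item["mis"] = {
                "xbar": Xm.mean(axis=0), "w": w, "s": np.sqrt(max(s2, 1e-12)),
                "u": float(u_lin.loc[blk["subject"]]),
            }
        pre.append(item)

    def nll(beta):
        total = 0.0
        for item in pre:
            r = item["yo"] - item["Xo"] @ beta
            if item["Vo_inv"] is not None:
                total -= 0.5 * r @ item["Vo_inv"] @ r
            mi = item["mis"]
            if mi is not None:
                a = mi["xbar"] @ beta + mi["w"] @ r
                vals = expit(mi["u"] + gamma * (a + np.sqrt(2.0) * mi["s"] * gh_x))
                total += np.log(max((gh_w * vals).sum() / np.sqrt(np.pi), 1e-300))
        return -total

    beta0 = fit.fe_table["estimate"].reindex(names).to_numpy()
    res = minimize(nll, beta0, method="BFGS", options={"maxiter": 500, "gtol": 1e-8})
    return pd.Series(res.x, index=names)
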