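"""Mixed-effects and regression inference for the two-modality biomarkers.

* Univariate linear mixed model for the evaluator-level latent EEG score:
  fixed effects intercept + group + age + group:age + sex + ecology, random
  intercepts for subjects (optionally crossed with evaluator), ML fitting so
  nested fixed-effect structures are comparable by likelihood ratio.
* Multivariate (two-outcome) mixed model: the outcomes are stacked in long
  format with a modality indicator; fixed effects are modality-specific, the
  subject random intercepts of the two modalities have an unstructured 2x2
  covariance, and each modality keeps its own residual variance.  statsmodels
  cannot fit per-modality residual variances, so this model carries its own
  profiled-GLS ML routine (variance parameters optimized numerically, fixed
  effects profiled out in closed form).
* Likelihood-ratio ANOVA of nested ML fits (L ratio = 2 * delta loglik,
  chi-squared reference).
* Covariate-adjusted standardized-beta association regressions, and the
  demographic two-group tests (pooled-variance t; 2x2 Pearson chi-squared
  with an optional Yates-corrected variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "LMEFit",
    "MLMEFit",
    "ModelComparison",
    "build_design",
    "fit_lme_univariate",
    "fit_mlme",
    "compare_models",
    "association_regression",
    "demographics_tests",
    "two_sample_t_from_summary",
    "chi2_2x2",
]

FIXED_TERMS = ("Intercept", "group[PEM]", "age", "age:group[PEM]", "sex[M]", "ecology")


def build_design(data):
    """Fixed-effect design matrix shared by the LME and the ISNI module."""
    X = pd.DataFrame({
        "Intercept": 1.0,
        "group[PEM]": (data["group"] == "PEM").astype(float),
        "age": data["age"].astype(float),
        "age:group[PEM]": data["age"].astype(float) * (data["group"] == "PEM"),
        "sex[M]": (data["sex"] == "M").astype(float),
        "ecology": data["ecology"].astype(float),
    }, index=data.index)
    return X


def _fe_table(names, est, se):
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "estimate": est, "se": se,
        "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
        "p": p,
    }, index=pd.Index(names, name="term"))


@dataclass
class LMEFit:
    label: str
    fe_table: pd.DataFrame
    vc: dict
    loglik: float
    n_free_params: int
    n_obs: int
    n_subjects: int
    resid_sd: float
    random_spec: str
    method: str = "ML"
    data: pd.DataFrame | None = field(default=None, repr=False)
    exog_names: tuple = FIXED_TERMS

    @property
    def aic(self):
        return 2 * self.n_free_params - 2 * self.loglik

    @property
    def bic(self):
        return self.n_free_params * np.log(self.n_obs) - 2 * self.loglik


def fit_lme_univariate(data, outcome="sqnps", random_spec="subject"):
    """ML fit of the univariate mixed model for a latent EEG score.

    ``data`` is long format (one row per subject x wave x evaluator) with
    columns subject_id, group, age, sex, ecology and the outcome.  With no
    repeated rows per subject the fit degenerates to OLS with a warning.
    """
    if random_spec not in ("subject", "subject+evaluator"):
        raise ValueError("random_spec must be 'subject' or 'subject+evaluator'")
    df = data.dropna(subset=[outcome]).copy()
    X = build_design(df)
    y = df[outcome].astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear fixed effects")

    n_per_subject = df.groupby("subject_id").size()
    if (n_per_subject <= 1).all():
        warnings.warn("no repeated measures; mixed model degenerates to OLS")
        ols = sm.OLS(y, X).fit()
        fe = _fe_table(X.columns, ols.params.to_numpy(), ols.bse.to_numpy())
        sd = float(np.sqrt(ols.scale))
        return LMEFit(label=f"{outcome}~fixed (OLS fallback)", fe_table=fe,
                      vc={"subject": 0.0, "residual": sd ** 2},
                      loglik=float(ols.llf), n_free_params=X.shape[1] + 1,
                      n_obs=len(df), n_subjects=df["subject_id"].nunique(),
                      resid_sd=sd, random_spec=random_spec, data=df)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if random_spec == "subject":
            model = sm.MixedLM(y, X, groups=df["subject_id"])
            res = model.fit(reml=False)
            vc = {"subject": float(res.cov_re.iloc[0, 0]),
                  "residual": float(res.scale)}
            n_free = X.shape[1] + 2
        else:
            frame = X.copy()
            frame["_y"] = y.to_numpy()
            frame["_subject"] = df["subject_id"].to_numpy()
            frame["_evaluator"] = df["evaluator"].to_numpy()
            frame["_one"] = 1
            frame = frame.rename(columns={
                "group[PEM]": "grp", "age:group[PEM]": "age_grp", "sex[M]": "sexM"})
            model = sm.MixedLM.from_formula(
                "_y ~ grp + age + age_grp + sexM + ecology",
                groups="_one", re_formula="0",
                vc_formula={"subject": "0 + C(_subject)",
                            "evaluator": "0 + C(_evaluator)"},
                data=frame)
            # powell is markedly more reliable than gradient methods for the
            # crossed variance-component parameterization (boundary at 0)
            res = model.fit(reml=False, method="powell", maxiter=5000)
            res_g = model.fit(reml=False, method="lbfgs", maxiter=2000)
            if res_g.llf > res.llf + 1e-8:
                res = res_g
            names = list(model.exog_vc.names)
            vc = {name: float(res.vcomp[i]) for i, name in enumerate(names)}
            vc["residual"] = float(res.scale)
            n_free = X.shape[1] + len(names) + 1
    for name, v in vc.items():
        if name != "residual" and v < 1e-8:
            warnings.warn(f"variance component {name!r} estimated at boundary (0)")
    fe = _fe_table(X.columns, np.asarray(res.fe_params), np.asarray(res.bse_fe))
    return LMEFit(label=f"{outcome}~group*age+sex+ecology ({random_spec})",
                  fe_table=fe, vc=vc, loglik=float(res.llf), n_free_params=n_free,
                  n_obs=len(df), n_subjects=df["subject_id"].nunique(),
                  resid_sd=float(np.sqrt(res.scale)), random_spec=random_spec,
                  data=df)


# ---------------------------------------------------------------------------
# Multivariate (two-outcome) mixed model
# ---------------------------------------------------------------------------

MODALITIES = ("qnps", "sqnps")
CONSTRAINTS = ("both", "qnps_only", "sqnps_only")


@dataclass
class MLMEFit:
    label: str
    constraint: str
    fe_table: pd.DataFrame
    psi: np.ndarray                  # 2x2 subject random-intercept covariance
    resid_sd: dict                   # per-modality residual SD
    subject_corr: float
    loglik: float
    n_free_params: int
    n_obs: int
    n_subjects: int
    method: str = "ML"

    @property
    def aic(self):
        return 2 * self.n_free_params - 2 * self.loglik

    @property
    def bic(self):
        return self.n_free_params * np.log(self.n_obs) - 2 * self.loglik


def _mlme_design(df, constraint):
    cols = {}
    for m in MODALITIES:
        ind = (df["modality"] == m).astype(float).to_numpy()
        cols[f"{m}:Intercept"] = ind
        if constraint == "both" or constraint == f"{m}_only":
            cols[f"{m}:group[PEM]"] = ind * (df["group"] == "PEM").to_numpy(float)
            cols[f"{m}:age"] = ind * df["age"].to_numpy(float)
            cols[f"{m}:age:group[PEM]"] = (ind * df["age"].to_numpy(float)
                                           * (df["group"] == "PEM").to_numpy(float))
            cols[f"{m}:sex[M]"] = ind * (df["sex"] == "M").to_numpy(float)
            cols[f"{m}:ecology"] = ind * df["ecology"].to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def _mlme_patterns(df, X):
    """Group subjects by their modality pattern for vectorized likelihood."""
    patterns = {}
    for sid, idx in df.groupby("subject_id").groups.items():
        sub = df.loc[idx].sort_values(["wave", "modality"])
        key = tuple(sub["modality"])
        patterns.setdefault(key, []).append(sub.index)
    out = []
    mod_code = {m: i for i, m in enumerate(MODALITIES)}
    for key, idx_list in patterns.items():
        k = len(key)
        Z = np.zeros((k, 2))
        codes = np.array([mod_code[m] for m in key])
        Z[np.arange(k), codes] = 1.0
        Xs = np.stack([X.loc[ix].to_numpy(float) for ix in idx_list])
        ys = np.stack([df.loc[ix, "y"].to_numpy(float) for ix in idx_list])
        out.append({"Z": Z, "codes": codes, "X": Xs, "y": ys, "n_sub": len(idx_list)})
    return out


def _mlme_profile(eta, blocks, p):
    """Profiled ML: GLS beta in closed form given variance parameters."""
    eta = np.clip(eta, -30.0, 30.0)
    sig2 = np.exp(eta[:2])
    L = np.array([[np.exp(eta[2]), 0.0], [eta[3], np.exp(eta[4])]])
    psi = L @ L.T
    A = np.zeros((p, p))
    c = np.zeros(p)
    q = 0.0
    logdet = 0.0
    n_total = 0
    for blk in blocks:
        V = blk["Z"] @ psi @ blk["Z"].T + np.diag(sig2[blk["codes"]])
        # tiny jitter keeps boundary fits (e.g. perfectly duplicated
        # outcomes, correlation -> 1) numerically well-posed
        V[np.diag_indices_from(V)] += 1e-8 * np.trace(V) / V.shape[0]
        try:
            chol = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        ld = 2.0 * np.log(np.diag(chol)).sum()
        Linv = np.linalg.inv(chol)
        Vinv = Linv.T @ Linv
        Xs, ys = blk["X"], blk["y"]
        A += np.einsum("mkp,kl,mlq->pq", Xs, Vinv, Xs)
        c += np.einsum("mkp,kl,ml->p", Xs, Vinv, ys)
        q += np.einsum("mk,kl,ml->", ys, Vinv, ys)
        logdet += blk["n_sub"] * ld
        n_total += blk["n_sub"] * len(blk["codes"])
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return None
    quad = q - 2 * beta @ c + beta @ A @ beta
    if quad < -1e-3 * n_total:   # catastrophic cancellation near singular V
        return None
    quad = max(quad, 0.0)
    ll = -0.5 * (n_total * np.log(2 * np.pi) + logdet + quad)
    return {"ll": ll, "beta": beta, "A": A, "psi": psi, "sig2": sig2, "n": n_total}


def _mlme_start(df):
    """Moment-based starting values for the variance parameters."""
    resid = {}
    psi_d = {}
    sub_means = {}
    for i, m in enumerate(MODALITIES):
        sub = df[df["modality"] == m]
        within = sub.groupby("subject_id")["y"].var().mean()
        if not np.isfinite(within) or within <= 0:
            within = max(float(sub["y"].var()) / 2, 1e-3)
        resid[m] = within
        means = sub.groupby("subject_id")["y"].mean()
        between = max(float(means.var()) - within / 2, 1e-3)
        psi_d[m] = between
        sub_means[m] = means
    both = pd.concat(sub_means, axis=1).dropna()
    cov = float(both.cov().iloc[0, 1]) if len(both) > 2 else 0.0
    v0, v1 = psi_d[MODALITIES[0]], psi_d[MODALITIES[1]]
    rho = np.clip(cov / np.sqrt(v0 * v1), -0.9, 0.9)
    l11 = np.sqrt(v0)
    l21 = rho * np.sqrt(v1)
    l22 = np.sqrt(max(v1 - l21 ** 2, 1e-4))
    return np.array([np.log(resid[MODALITIES[0]]), np.log(resid[MODALITIES[1]]),
                     np.log(l11), l21, np.log(l22)])


def fit_mlme(data, constraint="both", precision="high"):
    """Two-outcome mixed model on stacked long data.

    ``data`` columns: subject_id, wave, modality in {'qnps','sqnps'}, y,
    group, age, sex, ecology.  Rows with missing y are dropped (pairwise
    complete); the three constraint variants must be fitted on the same rows
    to be compared.  Constrained variants zero every non-intercept fixed
    effect of the suppressed modality but keep both intercepts and the full
    variance structure, so all three live on one likelihood scale.
    """
    if constraint not in CONSTRAINTS:
        raise ValueError(f"constraint must be one of {CONSTRAINTS}")
    df = data.dropna(subset=["y"]).reset_index(drop=True)
    if set(df["modality"]) - set(MODALITIES):
        raise ValueError(f"modality labels must be {MODALITIES}")
    n_both = df.groupby("subject_id")["modality"].nunique()
    if (n_both == 2).sum() < 2:
        raise ValueError("fewer than 2 subjects with both outcomes")
    X = _mlme_design(df, constraint)
    p = X.shape[1]
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise ValueError("collinear fixed effects in the multivariate design")
    blocks = _mlme_patterns(df, X)

    x0 = _mlme_start(df)

    def nll(eta):
        out = _mlme_profile(eta, blocks, p)
        return np.inf if out is None else -out["ll"]

    best = minimize(nll, x0, method="L-BFGS-B",
                    options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    if precision != "fast":
        res2 = minimize(nll, best.x, method="Nelder-Mead",
                        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if res2.fun < best.fun:
            best = res2
    out = _mlme_profile(best.x, blocks, p)
    if out is None:
        raise RuntimeError("multivariate mixed model failed to converge")

    cov_beta = np.linalg.inv(out["A"])
    fe = _fe_table(X.columns, out["beta"], np.sqrt(np.diag(cov_beta)))
    psi = out["psi"]
    corr = float(psi[0, 1] / np.sqrt(psi[0, 0] * psi[1, 1])) if psi[0, 0] > 0 and psi[1, 1] > 0 else np.nan
    return MLMEFit(label=f"MLME[{constraint}]", constraint=constraint,
                   fe_table=fe, psi=psi,
                   resid_sd={m: float(np.sqrt(out["sig2"][i]))
                             for i, m in enumerate(MODALITIES)},
                   subject_corr=corr, loglik=float(out["ll"]),
                   n_free_params=p + 5, n_obs=out["n"],
                   n_subjects=df["subject_id"].nunique())


@dataclass
class ModelComparison:
    label_reduced: str
    label_full: str
    loglik_reduced: float
    loglik_full: float
    l_ratio: float
    df: int
    p: float


def compare_models(fit_reduced, fit_full):
    """Likelihood-ratio ANOVA of two nested ML fits on identical rows."""
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError(
            f"fits use different rows ({fit_reduced.n_obs} vs {fit_full.n_obs}); "
            "likelihoods are not comparable")
    l_ratio = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    # different optimizers may disagree at the 4th decimal on a truly nested
    # pair; clamp only that numerical noise, never a real violation
    if -1e-3 < l_ratio < 0:
        l_ratio = 0.0
    df = fit_full.n_free_params - fit_reduced.n_free_params
    if df <= 0:
        p = 1.0 if abs(l_ratio) < 1e-8 else float("nan")
        df = max(df, 0)
    else:
        p = float(stats.chi2.sf(l_ratio, df))
    return ModelComparison(label_reduced=getattr(fit_reduced, "label", "reduced"),
                           label_full=getattr(fit_full, "label", "full"),
                           loglik_reduced=fit_reduced.loglik,
                           loglik_full=fit_full.loglik,
                           l_ratio=l_ratio, df=df, p=p)


# ---------------------------------------------------------------------------
# Associations and demographics
# ---------------------------------------------------------------------------

def association_regression(data, outcome="mf", predictor="sqnps",
                           covariates=("ecology", "sex", "age")):
    """OLS association with standardized betas.

    The outcome and all continuous predictors are z-scored; binary sex enters
    as a 0/1 male indicator.  Complete-case rows only.
    """
    cols = [outcome, predictor, *covariates]
    df = data.dropna(subset=[c for c in cols if c in data.columns]).copy()

    def zscore(v):
        s = v.std(ddof=1)
        if s <= 0:
            raise ValueError("zero-variance variable in association regression")
        return (v - v.mean()) / s

    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    X[predictor] = zscore(df[predictor].astype(float))
    for c in covariates:
        if c == "sex":
            X["sex[M]"] = (df["sex"] == "M").astype(float)
        else:
            X[c] = zscore(df[c].astype(float))
    y = zscore(df[outcome].astype(float))
    if len(df) <= X.shape[1]:
        raise ValueError("fewer observations than parameters")
    ols = sm.OLS(y, X).fit()
    tab = _fe_table(X.columns, ols.params.to_numpy(), ols.bse.to_numpy())
    # OLS small-sample p-values (t reference)
    tab["p"] = 2 * stats.t.sf(np.abs(ols.tvalues.to_numpy()), ols.df_resid)
    return tab


def two_sample_t_from_summary(n1, mean1, sd1, n2, mean2, sd2):
    """Pooled-variance two-sample t from printed summary statistics."""
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p)}


def chi2_2x2(table, yates=False):
    """Pearson chi-squared on a 2x2 table (Yates correction optional)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    res = stats.chi2_contingency(table, correction=yates)
    return {"chi2": float(res.statistic), "p": float(res.pvalue)}


def demographics_tests(cohort):
    """Two-group baseline comparison table (t or chi-squared per variable)."""
    groups = cohort.groupby("group")
    if set(groups.groups) != {"PEM", "CON"} or groups.size().min() == 0:
        raise ValueError("need non-empty PEM and CON groups")
    pem = cohort[cohort["group"] == "PEM"]
    con = cohort[cohort["group"] == "CON"]
    rows = []

    def add_t(name, col):
        t, p = stats.ttest_ind(pem[col], con[col], equal_var=True)
        rows.append({"variable": name,
                     "PEM": f"{pem[col].mean():.2f} ± {pem[col].std(ddof=1):.2f}",
                     "CON": f"{con[col].mean():.2f} ± {con[col].std(ddof=1):.2f}",
                     "test": "t", "statistic": float(t), "p": float(p)})

    def add_chi2(name, indicator):
        if indicator.nunique() < 2:   # degenerate margin: no variation at all
            k = int(indicator.sum())
            rows.append({"variable": name, "PEM": str(k), "CON": str(k),
                         "test": "chi2", "statistic": 0.0, "p": 1.0})
            return
        tab = np.array([
            [int(indicator[cohort["group"] == "PEM"].sum()),
             int((~indicator[cohort["group"] == "PEM"]).sum())],
            [int(indicator[cohort["group"] == "CON"].sum()),
             int((~indicator[cohort["group"] == "CON"]).sum())]])
        res = chi2_2x2(tab)
        rows.append({"variable": name,
                     "PEM": f"{tab[0, 0]} ({100 * tab[0, 0] / tab[0].sum():.1f}%)",
                     "CON": f"{tab[1, 0]} ({100 * tab[1, 0] / tab[1].sum():.1f}%)",
                     "test": "chi2", "statistic": res["chi2"], "p": res["p"]})

    add_chi2("Males (%)", cohort["sex"] == "M")
    add_t("Age, childhood (years)", "age_childhood")
    add_t("Age, adulthood (years)", "age_adulthood")
    add_chi2("Left-handedness (%)", cohort["handedness"] == "L")
    add_t("Childhood standard of living", "ecology")
    return pd.DataFrame(rows)
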