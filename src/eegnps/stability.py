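"""Stable sparse classification of two-group feature tables.

The procedure: (1) univariate screening of "independent significant
features" by pooled two-sample t (|t| >= threshold, default 2, roughly a
p < 0.05 screen); (2) repeated stratified 70% training draws, screening on
the draw, then elastic-net logistic regression with the penalty strength
chosen by internal cross-validation -- a feature counts as selected when its
coefficient is nonzero; (3) features selected in more than half of the
repetitions form the stable set; (4) an independent round of stratified
70/30 splits refits the elastic net on the stable set and yields a
distribution of test-set AUCs, a pointwise-median ROC on a fixed FPR grid,
and a Gaussian kernel density of the AUC samples (Silverman bandwidth);
(5) the stable spectral features are reduced to a single latent score by a
one-factor (first principal axis) extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV, LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit, StratifiedKFold
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "indfeat_screen",
    "stability_select",
    "crossval_auc",
    "qnps_factor",
    "SelectionResult",
    "AUCResult",
    "StableSparseClassifier",
    "OneFactorScores",
    "EmptyStableSetError",
]

FPR_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


class EmptyStableSetError(RuntimeError):
    """No feature survived stability selection; review the retain threshold."""


def _as_frame(X):
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])


def _binary_labels(y):
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return (y == classes[1]).astype(int), classes


def indfeat_screen(X, y, threshold=2.0):
    """Boolean keep-mask from per-feature pooled two-sample t statistics.

    Zero-variance features are excluded with a warning rather than an error.
    """
    Xf = _as_frame(X)
    yb, _ = _binary_labels(y)
    A = Xf.to_numpy(dtype=float)[yb == 1]
    B = Xf.to_numpy(dtype=float)[yb == 0]
    n1, n0 = len(A), len(B)
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 samples per class to screen")
    m1, m0 = A.mean(axis=0), B.mean(axis=0)
    v1 = A.var(axis=0, ddof=1)
    v0 = B.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    constant = Xf.to_numpy(dtype=float).var(axis=0) <= 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} zero-variance feature(s) excluded from screen")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    # zero pooled variance with distinct means = perfect separator (t -> inf)
    t = np.where((sp2 <= 0) & (m1 != m0), np.inf * np.sign(m1 - m0), t)
    keep = np.abs(t) >= threshold
    keep[constant] = False
    keep[~np.isfinite(t) & (sp2 > 0)] = False
    return keep


def _fit_enet(Xtr, ytr, l1_ratio, Cs, inner_cv, seed, max_iter=2000):
    """Standardize then elastic-net logistic with CV-chosen penalty."""
    scaler = StandardScaler().fit(Xtr)
    Xs = scaler.transform(Xtr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        if len(Cs) > 1:
            cv = StratifiedKFold(inner_cv, shuffle=True, random_state=seed)
            clf = LogisticRegressionCV(
                Cs=list(Cs), cv=cv, solver="saga", scoring="neg_log_loss",
                l1_ratios=[l1_ratio], max_iter=max_iter, tol=1e-3,
                random_state=seed, n_jobs=1)
        else:
            clf = LogisticRegression(
                C=Cs[0], penalty="elasticnet", solver="saga",
                l1_ratio=l1_ratio, max_iter=max_iter, tol=1e-3,
                random_state=seed)
        clf.fit(Xs, ytr)
    return scaler, clf


@dataclass
class SelectionResult:
    feature_names: list
    screened_count: np.ndarray       # reps in which the feature passed the screen
    selection_frequency: pd.Series   # fraction of reps with nonzero coefficient
    stable_set: list                 # frequency > retain_threshold
    n_reps: int
    retain_threshold: float
    seed: object = None

    def stable_at(self, threshold):
        """Stable set at a different retention threshold (monotone in it)."""
        return list(self.selection_frequency.index[self.selection_frequency > threshold])


@dataclass
class AUCResult:
    auc_samples: np.ndarray
    auc_mean: float
    auc_std: float
    median_roc: pd.DataFrame         # columns fpr, tpr
    auc_density: pd.DataFrame | None  # columns auc, density
    features: list
    n_cv: int
    seed: object = None


def stability_select(X, y, n_reps=1000, train_frac=0.7, screen_threshold=2.0,
                     retain_threshold=0.5, l1_ratio=0.5, Cs=(0.01, 0.1, 1.0, 10.0),
                     inner_cv=5, seed=None):
    """Resampled elastic-net selection with an IndFeat pre-screen per draw.

    Screening happens inside each repetition, on the training draw only, so
    no information from held-out rows leaks into later AUC evaluation.
    """
    Xf = _as_frame(X)
    yb, _ = _binary_labels(y)
    names = list(Xf.columns)
    ss = np.random.SeedSequence(seed)
    split_seed, enet_root = ss.spawn(2)
    splitter = StratifiedShuffleSplit(
        n_splits=n_reps, train_size=train_frac,
        random_state=int(split_seed.generate_state(1)[0] % (2 ** 31)))
    enet_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in enet_root.spawn(n_reps)]

    Xa = Xf.to_numpy(dtype=float)
    sel_count = np.zeros(len(names))
    scr_count = np.zeros(len(names))
    all_screened_out = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for rep, (tr, _) in enumerate(splitter.split(Xa, yb)):
            keep = indfeat_screen(Xa[tr], yb[tr], threshold=screen_threshold)
            scr_count += keep
            if not keep.any():
                all_screened_out += 1
                continue
            _, clf = _fit_enet(Xa[np.ix_(tr, np.flatnonzero(keep))], yb[tr],
                               l1_ratio, Cs, inner_cv, enet_seeds[rep])
            nz = np.abs(clf.coef_[0]) > 0
            sel_count[np.flatnonzero(keep)[nz]] += 1
    if all_screened_out > 0.9 * n_reps:
        warnings.warn("all features screened out in more than 90% of repetitions")
    freq = pd.Series(sel_count / n_reps, index=names, name="selection_frequency")
    stable = list(freq.index[freq > retain_threshold])
    return SelectionResult(feature_names=names, screened_count=scr_count,
                           selection_frequency=freq, stable_set=stable,
                           n_reps=n_reps, retain_threshold=retain_threshold,
                           seed=seed)


def crossval_auc(X, y, features=None, n_cv=1000, train_frac=0.7, l1_ratio=0.5,
                 Cs=(0.01, 0.1, 1.0, 10.0), inner_cv=5, seed=None):
    """AUC distribution over fresh stratified 70/30 splits on a feature set.

    Each split refits the elastic net on the training part only and scores
    the held-out rows.  Returns samples, their mean/SD, the pointwise-median
    ROC on a fixed FPR grid, and a Gaussian KDE of the AUC samples.
    """
    Xf = _as_frame(X)
    if features is not None:
        if len(features) == 0:
            raise EmptyStableSetError(
                "stable set is empty; review the retention/screen thresholds")
        Xf = Xf[list(features)]
    yb, _ = _binary_labels(y)
    Xa = Xf.to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed)
    split_seed, enet_root = ss.spawn(2)
    splitter = StratifiedShuffleSplit(
        n_splits=n_cv, train_size=train_frac,
        random_state=int(split_seed.generate_state(1)[0] % (2 ** 31)))
    enet_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in enet_root.spawn(n_cv)]

    aucs = np.empty(n_cv)
    tprs = np.empty((n_cv, FPR_GRID.size))
    for rep, (tr, te) in enumerate(splitter.split(Xa, yb)):
        scaler, clf = _fit_enet(Xa[tr], yb[tr], l1_ratio, Cs, inner_cv, enet_seeds[rep])
        scores = clf.decision_function(scaler.transform(Xa[te]))
        aucs[rep] = roc_auc_score(yb[te], scores)
        fpr, tpr, _ = roc_curve(yb[te], scores)
        tprs[rep] = np.interp(FPR_GRID, fpr, tpr)
    median_roc = pd.DataFrame({"fpr": FPR_GRID, "tpr": np.median(tprs, axis=0)})
    if np.std(aucs) > 0:
        kde = stats.gaussian_kde(aucs, bw_method="silverman")
        grid = np.linspace(max(0.0, aucs.min() - 0.05), min(1.0, aucs.max() + 0.05), 201)
        density = pd.DataFrame({"auc": grid, "density": kde(grid)})
    else:
        density = None
    return AUCResult(auc_samples=aucs, auc_mean=float(aucs.mean()),
                     auc_std=float(aucs.std(ddof=1)), median_roc=median_roc,
                     auc_density=density,
                     features=list(Xf.columns), n_cv=n_cv, seed=seed)


class OneFactorScores:
    """First-principal-axis scores of standardized features (one factor).

    Scores are standardized to mean 0, SD 1; the sign is oriented to
    correlate positively with a reference vector when one is given.
    """

    def __init__(self):
        pass

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X, y=None):
        Xf = _as_frame(X)
        if Xf.shape[1] < 2:
            raise ValueError("need >= 2 features for factor extraction")
        Xa = Xf.to_numpy(dtype=float)
        sd = Xa.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            raise ValueError("zero-variance feature in factor input")
        self.mean_ = Xa.mean(axis=0)
        self.scale_ = sd
        Z = (Xa - self.mean_) / self.scale_
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        if s[0] <= 1e-12:
            raise ValueError("rank-deficient input")
        self.components_ = Vt[0]
        self.feature_names_ = list(Xf.columns)
        raw = Z @ self.components_
        self.score_sd_ = raw.std(ddof=0)
        self.orientation_ = 1.0
        if y is not None:
            r = np.corrcoef(raw, np.asarray(y, dtype=float))[0, 1]
            if r < 0:
                self.orientation_ = -1.0
        return self

    def transform(self, X):
        Xf = _as_frame(X)[self.feature_names_]
        Z = (Xf.to_numpy(dtype=float) - self.mean_) / self.scale_
        raw = Z @ self.components_
        return self.orientation_ * (raw - raw.mean()) / self.score_sd_

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        # standardization contract: scores mean 0, SD 1 on the fitted data
        raw = ((_as_frame(X)[self.feature_names_].to_numpy(float) - self.mean_)
               / self.scale_) @ self.components_
        z = (raw - raw.mean()) / raw.std(ddof=0)
        return self.orientation_ * z


def qnps_factor(X, reference=None):
    """One-factor latent score of stable spectral features (the qNPS)."""
    return OneFactorScores().fit_transform(X, reference)


class StableSparseClassifier:
    """End-to-end stable sparse classifier (selection + CV-AUC + final fit).

    Composes :func:`stability_select` and :func:`crossval_auc`; after ``fit``
    the estimator carries ``selection_`` / ``evaluation_`` results, and
    ``predict`` uses an elastic net refit on the full data restricted to the
    stable set.
    """

    def __init__(self, n_reps=1000, n_cv=1000, train_frac=0.7,
                 screen_threshold=2.0, retain_threshold=0.5, l1_ratio=0.5,
                 Cs=(0.01, 0.1, 1.0, 10.0), inner_cv=5, random_state=None):
        self.n_reps = n_reps
        self.n_cv = n_cv
        self.train_frac = train_frac
        self.screen_threshold = screen_threshold
        self.retain_threshold = retain_threshold
        self.l1_ratio = l1_ratio
        self.Cs = Cs
        self.inner_cv = inner_cv
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "n_reps", "n_cv", "train_frac", "screen_threshold",
            "retain_threshold", "l1_ratio", "Cs", "inner_cv", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        Xf = _as_frame(X)
        yb, self.classes_ = _binary_labels(y)
        ss = np.random.SeedSequence(self.random_state)
        s_sel, s_cv, s_fin = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3)]
        self.selection_ = stability_select(
            Xf, yb, n_reps=self.n_reps, train_frac=self.train_frac,
            screen_threshold=self.screen_threshold,
            retain_threshold=self.retain_threshold, l1_ratio=self.l1_ratio,
            Cs=self.Cs, inner_cv=self.inner_cv, seed=s_sel)
        self.stable_features_ = self.selection_.stable_set
        self.selection_frequency_ = self.selection_.selection_frequency
        self.evaluation_ = crossval_auc(
            Xf, yb, features=self.stable_features_, n_cv=self.n_cv,
            train_frac=self.train_frac, l1_ratio=self.l1_ratio, Cs=self.Cs,
            inner_cv=self.inner_cv, seed=s_cv)
        self.auc_samples_ = self.evaluation_.auc_samples
        self.auc_mean_ = self.evaluation_.auc_mean
        self.auc_std_ = self.evaluation_.auc_std
        self._scaler, self._final = _fit_enet(
            Xf[self.stable_features_].to_numpy(float), yb, self.l1_ratio,
            self.Cs, self.inner_cv, s_fin)
        self._columns = list(Xf.columns)
        return self

    def decision_function(self, X):
        Xf = _as_frame(X)[self.stable_features_]
        return self._final.decision_function(self._scaler.transform(Xf.to_numpy(float)))

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]
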