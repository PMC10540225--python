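"""Polytomous item response theory for ordinal EEG ratings and cognition
subscales.

The generalized partial credit model (GPCM) gives, for an item with
discrimination a and step thresholds b_1..b_K,

    P(X = k | theta) = exp(sum_{v<=k} a (theta - b_v)) /
                       sum_m exp(sum_{v<=m} a (theta - b_v)),   empty sum = 0.

Fitting is by marginal maximum likelihood under a standard-normal latent
prior, with the integral approximated by fixed Gauss-Hermite quadrature and
the quadrature-approximated likelihood maximized numerically (direct
optimization; EM brings nothing at this item count).  Latent scores are EAP
(posterior mean on the quadrature grid), with missing items marginalized out.
Loadings use the 1.702 logistic-to-normal convention:
lambda_j = a*_j / sqrt(1 + a*_j^2), a*_j = a_j / 1.702.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "LOGISTIC_SCALING",
    "gpcm_category_probs",
    "GeneralizedPartialCreditModel",
    "fit_gpcm",
    "loadings",
    "eap_score",
    "trace_curves",
    "collapse_categories",
    "average_evaluators",
    "responses_to_matrix",
    "ConvergenceError",
]

LOGISTIC_SCALING = 1.702


class ConvergenceError(RuntimeError):
    """Marginal-likelihood optimization failed; message carries the trace."""


def _gpcm_logprobs(a, b, theta):
    """Log P(k | theta) for k = 0..K at each theta; shape (n_theta, K+1)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(b, dtype=float)
    steps = a * (theta[:, None] - b[None, :])          # (n_theta, K)
    cum = np.concatenate([np.zeros((theta.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    return cum - logsumexp(cum, axis=1, keepdims=True)


def gpcm_category_probs(a, b, theta):
    """Category probability vector(s) of length K+1; rows sum to one."""
    p = np.exp(_gpcm_logprobs(a, b, theta))
    return p[0] if np.isscalar(theta) else p


def loadings(discriminations):
    """Factor-analytic loading per item from GPCM discriminations."""
    a_star = np.asarray(discriminations, dtype=float) / LOGISTIC_SCALING
    return a_star / np.sqrt(1.0 + a_star ** 2)


def _gauss_hermite(n_nodes):
    """Nodes/log-weights for integrating against the standard normal."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), np.log(w) - 0.5 * np.log(np.pi)


class GeneralizedPartialCreditModel:
    """GPCM fitted by quadrature marginal ML; sklearn-style estimator.

    ``fit(X)`` takes an (n_respondents, n_items) array or DataFrame of
    ordinal responses (NaN allowed = item not administered); ``transform(X)``
    returns EAP latent scores.  Fitted attributes carry a trailing underscore.
    """

    def __init__(self, n_quadrature=61, max_iter=2000, compute_se=True, bound=10.0):
        self.n_quadrature = n_quadrature
        self.max_iter = max_iter
        self.compute_se = compute_se
        self.bound = bound

    def get_params(self, deep=True):
        return {"n_quadrature": self.n_quadrature, "max_iter": self.max_iter,
                "compute_se": self.compute_se, "bound": self.bound}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- internal -----------------------------------------------------------

    def _unpack(self, params):
        a = np.empty(len(self.n_categories_))
        bs = []
        pos = 0
        for j, k in enumerate(self.n_categories_):
            a[j] = params[pos]
            bs.append(params[pos + 1: pos + 1 + k])
            pos += 1 + k
        return a, bs

    def _pattern_loglik(self, params, X, nodes):
        """Per-respondent log-likelihood at each quadrature node, (n, Q)."""
        a, bs = self._unpack(params)
        L = np.zeros((X.shape[0], nodes.size))
        for j in range(X.shape[1]):
            lp = _gpcm_logprobs(a[j], bs[j], nodes)          # (Q, K+1)
            xj = X[:, j]
            obs = ~np.isnan(xj)
            idx = xj[obs].astype(int)
            L[obs] += lp[:, idx].T
        return L

    def _nll(self, params, X, nodes, logw):
        L = self._pattern_loglik(params, X, nodes)
        return -float(logsumexp(L + logw[None, :], axis=1).sum())

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.item_names_ = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            self.item_names_ = [f"item_{j}" for j in range(Xa.shape[1])]
        if Xa.ndim != 2 or Xa.shape[1] < 2:
            raise ValueError("need a 2-D response matrix with >= 2 items")
        n_cats = []
        for j, name in enumerate(self.item_names_):
            obs = Xa[:, j][~np.isnan(Xa[:, j])]
            if obs.size == 0 or np.unique(obs).size < 2:
                raise ValueError(
                    f"item {name!r} has fewer than 2 observed categories")
            if obs.min() < 0 or not np.allclose(obs, np.round(obs)):
                raise ValueError(f"item {name!r} has non-ordinal responses")
            n_cats.append(int(obs.max()))
        self.n_categories_ = n_cats

        nodes, logw = _gauss_hermite(self.n_quadrature)
        x0 = []
        for k in n_cats:
            x0.append(1.0)
            x0.extend(np.linspace(-1.0, 1.0, k))
        x0 = np.array(x0)
        bounds = [(-self.bound, self.bound)] * x0.size

        res = minimize(self._nll, x0, args=(Xa, nodes, logw),
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": self.max_iter, "maxfun": 10 * self.max_iter})
        if not res.success and np.max(np.abs(res.jac)) > 1e-2 * max(1.0, Xa.shape[0] / 100):
            raise ConvergenceError(
                f"GPCM optimization did not converge: {res.message} "
                f"(nit={res.nit}, |grad|max={np.max(np.abs(res.jac)):.3g})")

        params = res.x.copy()
        a, bs = self._unpack(params)
        self.orientation_flipped_ = bool(a.sum() < 0)
        if self.orientation_flipped_:
            # equivalent model under theta -> -theta; fix sign so that the
            # aggregate discrimination (higher score = more abnormality) is
            # positive
            a, bs = -a, [-b for b in bs]
        self.discrimination_ = a
        self.thresholds_ = [np.asarray(b) for b in bs]
        self.loglik_ = -res.fun
        self.n_parameters_ = int(x0.size)
        n = Xa.shape[0]
        self.n_respondents_ = n
        self.aic_ = 2 * self.n_parameters_ - 2 * self.loglik_
        self.bic_ = self.n_parameters_ * np.log(n) - 2 * self.loglik_
        self.loadings_ = loadings(self.discrimination_)
        self.quad_nodes_ = nodes
        self.quad_logw_ = logw
        self._packed = self._pack(a, bs)
        if self.compute_se:
            self._observed_information(Xa, nodes, logw)
        else:
            self.se_discrimination_ = None
            self.se_thresholds_ = None
        return self

    def _pack(self, a, bs):
        out = []
        for j in range(len(a)):
            out.append(a[j])
            out.extend(bs[j])
        return np.array(out)

    def _observed_information(self, X, nodes, logw):
        p = self._packed
        h = 1e-4 * np.maximum(1.0, np.abs(p))
        m = p.size
        H = np.empty((m, m))
        f0 = self._nll(p, X, nodes, logw)
        fp = np.empty(m)
        fm = np.empty(m)
        for i in range(m):
            e = np.zeros(m); e[i] = h[i]
            fp[i] = self._nll(p + e, X, nodes, logw)
            fm[i] = self._nll(p - e, X, nodes, logw)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(m):
            for j in range(i + 1, m):
                e_i = np.zeros(m); e_i[i] = h[i]
                e_j = np.zeros(m); e_j[j] = h[j]
                fpp = self._nll(p + e_i + e_j, X, nodes, logw)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:  # pragma: no cover
            warnings.warn("observed information singular; SEs unavailable")
            se = np.full(m, np.nan)
        a_se, b_se = self._unpack(se)
        self.se_discrimination_ = a_se
        self.se_thresholds_ = [np.asarray(b) for b in b_se]

    def transform(self, X):
        """EAP latent score per respondent (missing items marginalized)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.item_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if np.all(np.isnan(X)):
            raise ValueError("empty response pattern")
        L = self._pattern_loglik(self._packed, X, self.quad_nodes_)
        logpost = L + self.quad_logw_[None, :]
        logpost -= logsumexp(logpost, axis=1, keepdims=True)
        return np.exp(logpost) @ self.quad_nodes_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def category_probs(self, item, theta):
        j = self.item_names_.index(item) if isinstance(item, str) else item
        return gpcm_category_probs(self.discrimination_[j], self.thresholds_[j], theta)

    def to_dict(self):
        """JSON-serializable model summary."""
        return {
            "items": self.item_names_,
            "discrimination": self.discrimination_.tolist(),
            "thresholds": [b.tolist() for b in self.thresholds_],
            "loadings": self.loadings_.tolist(),
            "loglik": self.loglik_,
            "aic": self.aic_,
            "bic": self.bic_,
            "n_parameters": self.n_parameters_,
            "n_respondents": self.n_respondents_,
            "n_quadrature": self.n_quadrature,
            "orientation": "higher score = more abnormality",
            "orientation_flipped": self.orientation_flipped_,
        }


def fit_gpcm(responses, **kwargs):
    """Fit a :class:`GeneralizedPartialCreditModel` on a wide response table."""
    return GeneralizedPartialCreditModel(**kwargs).fit(responses)


def eap_score(model, pattern):
    """EAP score for one response pattern (array/Series over model items)."""
    if isinstance(pattern, dict):
        pattern = [pattern.get(name, np.nan) for name in model.item_names_]
    return float(model.transform(np.asarray(pattern, dtype=float))[0])


def trace_curves(model, theta_grid):
    """Tidy table of P(category | theta) per item over a latent grid."""
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("empty theta grid")
    frames = []
    for j, name in enumerate(model.item_names_):
        p = gpcm_category_probs(model.discrimination_[j], model.thresholds_[j], theta_grid)
        for k in range(p.shape[1]):
            frames.append(pd.DataFrame({
                "item": name, "category": k, "theta": theta_grid, "prob": p[:, k]}))
    return pd.concat(frames, ignore_index=True)


def collapse_categories(responses, mapping):
    """Remap ordinal categories (e.g. merge rarely used top levels).

    ``mapping`` is {item: {old: new}}; each item map must be order-preserving
    (non-decreasing in the old category) and surjective onto 0..new_max.
    Returns the remapped long table (same columns).
    """
    out = responses.copy()
    for item, m in mapping.items():
        keys = sorted(m)
        vals = [m[k] for k in keys]
        if any(v2 < v1 for v1, v2 in zip(vals, vals[1:])):
            raise ValueError(f"non-monotone category mapping for {item!r}")
        if sorted(set(vals)) != list(range(max(vals) + 1)):
            raise ValueError(f"mapping for {item!r} is not onto 0..{max(vals)}")
        sel = out["item"] == item
        observed = set(out.loc[sel, "response"].unique())
        missing_keys = observed - set(keys)
        if missing_keys:
            raise ValueError(f"mapping for {item!r} lacks categories {sorted(missing_keys)}")
        out.loc[sel, "response"] = out.loc[sel, "response"].map(m)
    return out


def responses_to_matrix(responses, items=None,
                        index=("subject_id", "wave", "evaluator")):
    """Pivot a long response table to a wide (respondent x item) matrix."""
    wide = responses.pivot_table(index=list(index), columns="item",
                                 values="response", aggfunc="first")
    if items is not None:
        wide = wide.reindex(columns=list(items))
    return wide


def average_evaluators(scores, value="sqnps", index=("subject_id", "wave")):
    """Arithmetic mean of the available evaluators' latent scores."""
    if len(scores) == 0:
        raise ValueError("no scores to average")
    out = scores.groupby(list(index), as_index=False)[value].mean()
    if out[value].isna().any():
        raise ValueError("missing scores for some subject/wave cells")
    return out
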