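"""Regression-mixture decomposition of gaze time headway.

In (time-into-trial, TH) coordinates a fixated world point traces a
line of slope -1 (TH falls at exactly the rate trial time rises), while
gaze that stays a fixed preview time ahead of the moving observer is
independent of trial time.  The decomposition exploits this: gaze TH is
modelled as a weighted mixture of regression components with *fixed*
slopes,

* **GF** (guiding fixations): slope 0, free intercept ``mu_GF`` (the
  mean preview time, seconds) and free sd ``sigma_GF``;
* **EF** (entry fixations): slope -1, free intercept ``c_EF`` — the
  time-along-midline position of a single principal attractor point
  just past the bend entry — and free sd ``sigma_EF``;
* **noise**: a fixed density (uniform over [0, th_max]) that absorbs
  off-task outliers so they cannot skew the two structural clusters.

Only four parameters are free per fit (two intercepts, two sds) plus
the mixing weights.  The model is fitted by expectation-maximisation,
restarted from a sparse grid of initial values with the highest-
likelihood fit retained; every gaze sample receives a responsibility
vector over (GF, EF, noise) rather than a hard label.  Because the two
structural components have structurally different slopes there is no
label-switching ambiguity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_is_fitted

_LOG2PI = np.log(2 * np.pi)


class DataSparsityError(ValueError):
    """Too few included samples for a stable mixture fit."""


class MixtureFitError(RuntimeError):
    """All initialisations failed; carries per-init diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class MixtureInit:
    """One EM starting point."""

    mu_gf: float
    c_ef: float
    sigma_gf: float = 0.5
    sigma_ef: float = 0.5
    weights: tuple = (0.6, 0.3, 0.1)


def default_init_grid(bend_entry_time_s: float,
                      mu_gf_values=(1.5, 2.0, 2.5),
                      c_ef_offsets=(0.5, 1.0, 1.5)) -> list[MixtureInit]:
    """Sparse 3x3 grid spanning plausible preview times (GF around 2 s)
    and attractor locations (0.5-1.5 s past the bend entry)."""
    return [MixtureInit(mu_gf=m, c_ef=bend_entry_time_s + o)
            for m, o in itertools.product(mu_gf_values, c_ef_offsets)]


class GazeTHMixture(DensityMixin, BaseEstimator):
    """EM-fitted GF/EF/noise mixture over (time_into_trial, TH) samples.

    Parameters
    ----------
    init : MixtureInit or sequence of MixtureInit, optional
        Starting point(s).  A sequence triggers a grid fit: EM runs from
        every element and the highest-likelihood converged fit is kept.
        Default: the 3x3 grid of :func:`default_init_grid` anchored at
        ``bend_entry_time_s``.
    bend_entry_time_s : float, default 5.0
        Trial time of the bend entry; anchors the default ``c_EF`` grid.
    th_max_s : float, default 8.0
        Upper support of the fixed uniform noise density (matches the
        forward search window of the TH estimator).
    tol : float, default 1e-6
        Absolute log-likelihood change below which EM stops.
    max_iter : int, default 500
    min_samples : int, default 50
        Fits on fewer samples are refused (sparse data biases the fit).
    min_sigma : float, default 0.01
        A component whose sd collapses below this is pruned to weight 0
        and flagged in ``pruned_``.

    Attributes
    ----------
    mu_gf_, sigma_gf_ : float — GF intercept (mean preview TH) and sd.
    c_ef_, sigma_ef_ : float — attractor time-along-midline and sd.
    weights_ : (3,) ndarray — (GF, EF, noise) mixing weights.
    responsibilities_ : (n, 3) ndarray — per-sample posteriors.
    log_likelihood_ : float;  n_iter_ : int;  init_id_ : int.
    log_likelihood_path_ : per-iteration log-likelihood of the winning run.
    candidate_log_likelihoods_ : all grid candidates, for audit.
    pruned_ : set of pruned component names.

    Fitting is deterministic: there is no randomness inside EM.
    """

    def __init__(self, init=None, bend_entry_time_s: float = 5.0,
                 th_max_s: float = 8.0, tol: float = 1e-6,
                 max_iter: int = 500, min_samples: int = 50,
                 min_sigma: float = 0.01):
        self.init = init
        self.bend_entry_time_s = bend_entry_time_s
        self.th_max_s = th_max_s
        self.tol = tol
        self.max_iter = max_iter
        self.min_samples = min_samples
        self.min_sigma = min_sigma

    # ------------------------------------------------------------------
    def _inits(self) -> list[MixtureInit]:
        if self.init is None:
            return default_init_grid(self.bend_entry_time_s)
        if isinstance(self.init, MixtureInit):
            return [self.init]
        return list(self.init)

    def _component_logdens(self, x, th, mu_gf, c_ef, sig_gf, sig_ef):
        """(n, 3) per-component log densities at the current parameters."""
        n = len(th)
        out = np.empty((n, 3))
        out[:, 0] = -0.5 * (((th - mu_gf) / sig_gf) ** 2 + _LOG2PI) - np.log(sig_gf)
        out[:, 1] = -0.5 * (((th - (c_ef - x)) / sig_ef) ** 2 + _LOG2PI) - np.log(sig_ef)
        out[:, 2] = np.where((th >= 0) & (th <= self.th_max_s),
                             -np.log(self.th_max_s), -np.inf)
        return out

    def _em_single(self, x, th, init: MixtureInit):
        mu_gf, c_ef = init.mu_gf, init.c_ef
        sig_gf, sig_ef = init.sigma_gf, init.sigma_ef
        w = np.asarray(init.weights, dtype=float)
        w = w / w.sum()
        pruned: set[str] = set()
        ll_path = []
        ll_old = -np.inf
        resp = None
        for it in range(1, self.max_iter + 1):
            # E-step
            logd = self._component_logdens(x, th, mu_gf, c_ef, sig_gf, sig_ef)
            with np.errstate(divide="ignore"):
                logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
            joint = logd + logw
            norm = logsumexp(joint, axis=1)
            ll = float(norm.sum())
            resp = np.exp(joint - norm[:, None])
            ll_path.append(ll)
            if ll - ll_old < self.tol and it > 1:
                break
            ll_old = ll
            # M-step
            nk = resp.sum(axis=0)
            w = nk / nk.sum()
            if nk[0] > 0:
                mu_gf = float(resp[:, 0] @ th / nk[0])
                sig_gf = float(np.sqrt(resp[:, 0] @ (th - mu_gf) ** 2 / nk[0]))
            if nk[1] > 0:
                c_ef = float(resp[:, 1] @ (th + x) / nk[1])
                sig_ef = float(np.sqrt(resp[:, 1] @ (th - (c_ef - x)) ** 2 / nk[1]))
            # prune collapsed components rather than chase degenerate spikes
            if sig_gf < self.min_sigma and "gf" not in pruned:
                pruned.add("gf"); w[0] = 0.0; sig_gf = self.min_sigma
                w = w / w.sum()
            if sig_ef < self.min_sigma and "ef" not in pruned:
                pruned.add("ef"); w[1] = 0.0; sig_ef = self.min_sigma
                w = w / w.sum()
        return {
            "mu_gf": mu_gf, "c_ef": c_ef, "sigma_gf": sig_gf,
            "sigma_ef": sig_ef, "weights": w, "resp": resp,
            "ll": ll_path[-1], "n_iter": len(ll_path),
            "ll_path": np.asarray(ll_path), "pruned": pruned,
        }

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit to samples ``X`` of shape (n, 2): columns
        (time_into_trial_s, th_s)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: time_into_trial_s, th_s")
        if len(X) < self.min_samples:
            raise DataSparsityError(
                f"mixture fit refused: {len(X)} samples < {self.min_samples};"
                " sparse data biases the cluster estimates")
        x, th = X[:, 0], X[:, 1]

        results, failures = [], []
        for i, init in enumerate(self._inits()):
            try:
                res = self._em_single(x, th, init)
                res["init_id"] = i
                results.append(res)
            except FloatingPointError as exc:  # pragma: no cover
                failures.append((i, repr(exc)))
        if not results:
            raise MixtureFitError("all EM initialisations failed", failures)

        best = max(results, key=lambda r: r["ll"])
        self.mu_gf_ = best["mu_gf"]
        self.c_ef_ = best["c_ef"]
        self.sigma_gf_ = best["sigma_gf"]
        self.sigma_ef_ = best["sigma_ef"]
        self.weights_ = best["weights"]
        self.responsibilities_ = best["resp"]
        self.log_likelihood_ = best["ll"]
        self.log_likelihood_path_ = best["ll_path"]
        self.n_iter_ = best["n_iter"]
        self.init_id_ = best["init_id"]
        self.pruned_ = best["pruned"]
        self.candidate_log_likelihoods_ = [r["ll"] for r in results]
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X):
        """Responsibility vectors (posterior component probabilities)."""
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        logd = self._component_logdens(X[:, 0], X[:, 1], self.mu_gf_,
                                       self.c_ef_, self.sigma_gf_, self.sigma_ef_)
        with np.errstate(divide="ignore"):
            logw = np.where(self.weights_ > 0,
                            np.log(np.where(self.weights_ > 0, self.weights_, 1.0)),
                            -np.inf)
        joint = logd + logw
        return np.exp(joint - logsumexp(joint, axis=1)[:, None])

    def score_samples(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        logd = self._component_logdens(X[:, 0], X[:, 1], self.mu_gf_,
                                       self.c_ef_, self.sigma_gf_, self.sigma_ef_)
        with np.errstate(divide="ignore"):
            logw = np.where(self.weights_ > 0,
                            np.log(np.where(self.weights_ > 0, self.weights_, 1.0)),
                            -np.inf)
        return logsumexp(logd + logw, axis=1)

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))


# ----------------------------------------------------------------------
# functional wrappers and summaries


def em_fit(samples, init: MixtureInit, **kwargs) -> GazeTHMixture:
    """Single-initialisation EM fit (thin wrapper over GazeTHMixture)."""
    return GazeTHMixture(init=init, **kwargs).fit(np.asarray(samples))


def grid_fit(samples, init_grid=None, **kwargs) -> GazeTHMixture:
    """Grid-initialised EM: best-likelihood fit over all starting points."""
    if init_grid is not None and len(init_grid) == 0:
        raise ValueError("init_grid must be non-empty")
    return GazeTHMixture(init=init_grid, **kwargs).fit(np.asarray(samples))


@dataclass(frozen=True)
class ClusterSummary:
    """Per-fit summary in the units of the downstream condition
    comparisons (seconds of TH; weights renormalised without noise)."""

    gf_mean_th: float
    ef_mean_th: float
    composed_mean_th: float
    gf_weight: float
    ef_weight: float
    ef_point_time_s: float
    inverted: bool  # flagged when ef_mean_th <= gf_mean_th


def summarise_fit(fit: GazeTHMixture, samples) -> ClusterSummary:
    """Responsibility-weighted cluster means of the *observed* TH values.

    The composed mean is the weight-averaged GF/EF mean with the noise
    component excluded from the renormalisation.
    """
    check_is_fitted(fit, "weights_")
    X = np.asarray(samples, dtype=float)
    th = X[:, 1]
    resp = fit.predict_proba(X)
    nk = resp.sum(axis=0)
    gf_mean = float(resp[:, 0] @ th / nk[0]) if nk[0] > 0 else np.nan
    ef_mean = float(resp[:, 1] @ th / nk[1]) if nk[1] > 0 else np.nan
    w_gf, w_ef = fit.weights_[0], fit.weights_[1]
    denom = w_gf + w_ef
    if denom > 0:
        gf_w, ef_w = w_gf / denom, w_ef / denom
    else:
        gf_w = ef_w = np.nan
    if np.isnan(ef_mean):
        composed = gf_mean
    elif np.isnan(gf_mean):
        composed = ef_mean
    else:
        composed = gf_w * gf_mean + ef_w * ef_mean
    return ClusterSummary(
        gf_mean_th=gf_mean, ef_mean_th=ef_mean, composed_mean_th=composed,
        gf_weight=gf_w, ef_weight=ef_w, ef_point_time_s=fit.c_ef_,
        inverted=bool(np.isfinite(ef_mean) and np.isfinite(gf_mean)
                      and ef_mean <= gf_mean),
    )


def weights_along_track(fit: GazeTHMixture, samples, bandwidth_s: float = 0.5,
                        eval_times=None):
    """Kernel-smoothed cluster weights as a function of time into trial.

    Nadaraya-Watson average of the responsibility vectors with a
    Gaussian kernel of sd ``bandwidth_s``.  Because each responsibility
    row sums to one, the three smoothed curves sum to one everywhere.

    Returns ``(eval_times, curves)`` with ``curves`` of shape (m, 3).
    """
    X = np.asarray(samples, dtype=float)
    x = X[:, 0]
    resp = fit.predict_proba(X)
    if eval_times is None:
        eval_times = np.linspace(x.min(), x.max(), 200)
    eval_times = np.asarray(eval_times, dtype=float)
    d = (eval_times[:, None] - x[None, :]) / bandwidth_s
    k = np.exp(-0.5 * d * d)
    k /= k.sum(axis=1, keepdims=True)
    return eval_times, k @ resp
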