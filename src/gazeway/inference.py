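"""Bayesian condition comparisons.

Participant-level summaries (medians for skewed pooled measures,
fitted values for mixture summaries) feed a small hierarchical normal
model per measure:

    value[p, c] ~ Normal(mu[c], sigma)
    mu[c]       ~ Normal(prior_center, 1)       (weakly informative)
    sigma       ~ HalfNormal(1)

with one mean per driving mode (Manual, Auto-Replay, Auto-Stock) and a
shared residual sd (a per-condition sd variant is available behind a
flag).  The posterior is sampled with an affine-invariant ensemble
sampler (emcee); condition means, pairwise contrasts, 95% highest
density intervals and the posterior mass above zero are reported per
draw.  Convergence is gated on split-R-hat < 1.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd

MODES = ("Manual", "Auto-Replay", "Auto-Stock")
CONTRASTS = (("Auto-Replay", "Manual"), ("Auto-Stock", "Manual"),
             ("Auto-Stock", "Auto-Replay"))

#: Prior centres per measure family (seconds for TH measures and
#: durations, probability for weights).
PRIOR_CENTERS = {
    "median_th": 2.0, "gf_mean": 2.0, "ef_mean": 2.0,
    "launch_th": 2.0, "land_th": 2.0,
    "tracking_duration": 0.4,
    "gf_weight": 0.5,
}


class ConvergenceError(RuntimeError):
    """Sampler failed the R-hat gate; diagnostics attached."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


def summarise_participants(samples: pd.DataFrame, value_col: str,
                           measure: str,
                           by=("participant", "mode"),
                           agg: str = "median") -> pd.DataFrame:
    """Aggregate sample- or event-level rows to one value per
    participant x mode.

    Medians are the default aggregate: pooled TH and duration
    distributions are right-skewed, so the participant median is the
    robust summary the condition model consumes.  Participants with no
    rows in a mode are simply absent (a warning is emitted).
    """
    df = samples.dropna(subset=[value_col])
    grouped = df.groupby(list(by), observed=True)[value_col].agg(agg).reset_index()
    grouped = grouped.rename(columns={value_col: "value"})
    grouped.insert(len(by), "measure", measure)
    n_expected = df["participant"].nunique() * df["mode"].nunique()
    if len(grouped) < n_expected:
        warnings.warn(f"{measure}: {n_expected - len(grouped)} "
                      "participant x mode cells have no data and were omitted")
    return grouped


@dataclass
class PosteriorSummary:
    """Posterior means, 95% HDIs and contrast summaries for one measure."""

    measure: str
    condition_means: dict          # mode -> (mean, hdi_lo, hdi_hi)
    contrasts: dict                # "A - B" -> (mean, hdi_lo, hdi_hi, p_gt0)
    draws: dict = field(repr=False, default_factory=dict)  # mode -> 1-d draws
    rhat_max: float = np.nan
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mode, (m, lo, hi) in self.condition_means.items():
            rows.append({"measure": self.measure, "term": mode, "kind": "mean",
                         "mean": m, "hdi_2.5%": lo, "hdi_97.5%": hi,
                         "p_gt_zero": np.nan})
        for name, (m, lo, hi, p) in self.contrasts.items():
            rows.append({"measure": self.measure, "term": name, "kind": "contrast",
                         "mean": m, "hdi_2.5%": lo, "hdi_97.5%": hi,
                         "p_gt_zero": p})
        return pd.DataFrame(rows)


def _log_posterior(theta, values, cond_idx, n_cond, prior_center,
                   per_condition_sigma):
    """Vectorised over walkers: theta is (nwalkers, ndim)."""
    theta = np.atleast_2d(theta)
    mus = theta[:, :n_cond]
    sigmas = theta[:, n_cond:]
    out = np.full(len(theta), -np.inf)
    ok = np.all(sigmas > 0, axis=1) & np.all(sigmas < 50, axis=1)
    if not np.any(ok):
        return out
    mu_ok, sig_ok = mus[ok], sigmas[ok]
    mu_i = mu_ok[:, cond_idx]                        # (nok, ndata)
    sig_i = (sig_ok[:, cond_idx] if per_condition_sigma
             else np.broadcast_to(sig_ok, (sig_ok.shape[0], len(cond_idx))))
    resid = (values[None, :] - mu_i) / sig_i
    loglik = np.sum(-0.5 * resid ** 2 - np.log(sig_i), axis=1)
    # priors: mu ~ N(center, 1), sigma ~ HalfNormal(1)
    logprior = np.sum(-0.5 * (mu_ok - prior_center) ** 2, axis=1) \
        + np.sum(-0.5 * sig_ok ** 2, axis=1)
    out[ok] = loglik + logprior
    return out


def fit_condition_model(summaries: pd.DataFrame,
                        measure: str | None = None,
                        prior_center: float | None = None,
                        per_condition_sigma: bool = False,
                        n_chains: int = 4, n_walkers: int = 16,
                        n_warmup: int = 500,
                        n_steps: int = 800, seed: int = 0,
                        rhat_threshold: float = 1.01,
                        check_convergence: bool = True) -> PosteriorSummary:
    """Sample the hierarchical normal model for one measure.

    ``summaries`` needs columns participant, mode, value (and measure,
    when more than one is present).  Requires at least two participants
    per condition.  ``n_chains`` independent ensembles are run
    (differential-evolution moves, ``n_warmup`` discarded steps,
    ``n_steps`` kept steps of ``n_walkers`` walkers each); R-hat is
    computed *between* the independent ensembles, which is a stricter
    check than walker-wise splits, and the returned draw arrays pool
    everything (51 200 draws at the defaults).
    """
    df = summaries.dropna(subset=["value"])
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    elif measure is None and "measure" in df.columns and df["measure"].nunique() == 1:
        measure = df["measure"].iloc[0]
    modes = [m for m in MODES if m in set(df["mode"])]
    if len(modes) < 2:
        raise ValueError("need at least two driving modes to contrast")
    counts = df.groupby("mode", observed=True)["value"].count()
    if (counts[modes] < 2).any():
        raise ValueError("need >= 2 participants per condition")
    if prior_center is None:
        prior_center = PRIOR_CENTERS.get(measure or "", float(df["value"].mean()))

    values = df["value"].to_numpy(dtype=float)
    cond_idx = np.array([modes.index(m) for m in df["mode"]])
    n_cond = len(modes)
    n_sigma = n_cond if per_condition_sigma else 1
    ndim = n_cond + n_sigma

    grand = float(values.mean())
    sd0 = max(float(values.std(ddof=1)), 1e-3)
    chains = []
    accept = []
    for c in range(n_chains):
        rng = np.random.RandomState(
            np.random.SeedSequence([seed, c]).generate_state(1)[0] % (2**31))
        start = np.empty((n_walkers, ndim))
        jit = max(0.1 * sd0, 1e-2)   # floor keeps walkers well-conditioned
        start[:, :n_cond] = grand + jit * rng.randn(n_walkers, n_cond)
        start[:, n_cond:] = np.abs(sd0 * (1 + 0.1 * rng.randn(n_walkers, n_sigma))) \
            + 1e-3 * np.abs(rng.randn(n_walkers, n_sigma))
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, _log_posterior,
            args=(values, cond_idx, n_cond, prior_center, per_condition_sigma),
            vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8),
                   (emcee.moves.DESnookerMove(), 0.2)])
        sampler._random = rng
        sampler.run_mcmc(start, n_warmup + n_steps, progress=False)
        chains.append(sampler.get_chain(discard=n_warmup).reshape(-1, ndim))
        accept.append(sampler.acceptance_fraction)
    arr = np.stack(chains)                           # (n_chains, n, ndim)

    rhat_vals = np.array([float(az.rhat(arr[:, :, d])) for d in range(ndim)])
    rhat_max = float(np.nanmax(rhat_vals))
    if check_convergence and rhat_max > rhat_threshold:
        raise ConvergenceError(
            f"R-hat {rhat_max:.4f} exceeds {rhat_threshold}",
            diagnostics={"rhat": rhat_vals,
                         "acceptance_fraction": np.concatenate(accept)})

    flat = arr.reshape(-1, ndim)
    draws = {m: flat[:, i] for i, m in enumerate(modes)}

    def hdi95(x):
        lo, hi = az.hdi(np.asarray(x), hdi_prob=0.95)
        return float(lo), float(hi)

    cond_means = {m: (float(d.mean()), *hdi95(d)) for m, d in draws.items()}
    contrasts = {}
    for a, b in CONTRASTS:
        if a in draws and b in draws:
            d = draws[a] - draws[b]
            contrasts[f"{a} - {b}"] = (float(d.mean()), *hdi95(d),
                                       float(np.mean(d > 0)))
    return PosteriorSummary(measure=measure or "", condition_means=cond_means,
                            contrasts=contrasts, draws=draws,
                            rhat_max=rhat_max, seed=seed)


class ConditionContrastModel:
    """Estimator-style facade over :func:`fit_condition_model`.

    ``fit`` expects the participant-summary table; fitted attributes
    are ``posterior_`` (a :class:`PosteriorSummary`), plus the
    convenience ``condition_means_`` and ``contrasts_`` dicts.
    """

    def __init__(self, measure: str | None = None,
                 prior_center: float | None = None,
                 per_condition_sigma: bool = False,
                 n_chains: int = 4, n_walkers: int = 16,
                 n_warmup: int = 500, n_steps: int = 800, seed: int = 0,
                 rhat_threshold: float = 1.01,
                 check_convergence: bool = True):
        self.measure = measure
        self.prior_center = prior_center
        self.per_condition_sigma = per_condition_sigma
        self.n_chains = n_chains
        self.n_walkers = n_walkers
        self.n_warmup = n_warmup
        self.n_steps = n_steps
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.check_convergence = check_convergence

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "measure", "prior_center", "per_condition_sigma", "n_chains",
            "n_walkers", "n_warmup", "n_steps", "seed", "rhat_threshold",
            "check_convergence")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        self.posterior_ = fit_condition_model(
            X, measure=self.measure, prior_center=self.prior_center,
            per_condition_sigma=self.per_condition_sigma,
            n_chains=self.n_chains, n_walkers=self.n_walkers,
            n_warmup=self.n_warmup, n_steps=self.n_steps, seed=self.seed,
            rhat_threshold=self.rhat_threshold,
            check_convergence=self.check_convergence)
        self.condition_means_ = self.posterior_.condition_means
        self.contrasts_ = self.posterior_.contrasts
        return self
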