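"""Marginal likelihoods, Bayes factors and posterior model probabilities.

The marginal likelihood Pr(y | model) is approximated from posterior draws
by reciprocal importance sampling: with a light-tailed importance density
f over the parameter vector,

    Pr(y) ~ ( (1/c) * sum_i f(w_i) / [ Pr(y | w_i) * Pr(w_i) ] )^(-1),

evaluated entirely in log space. f is a multivariate t with c degrees of
freedom, centered at the posterior mean, with the correlation matrix of
the draws as its scale (the covariance matrix is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_t

from .data import CaptureHistory, StateSpace
from .detection import ModelSpec, integrated_loglik
from .mcmc import PosteriorSamples, free_parameters, params_from_row

__all__ = [
    "ImportanceDensity",
    "gd_log_marginal",
    "scr_log_marginal",
    "compare_models",
]


@dataclass(frozen=True)
class ImportanceDensity:
    """Multivariate-t importance density over the parameter vector."""

    df: float
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        scale = np.atleast_2d(np.asarray(self.scale, dtype=float))
        center = np.atleast_1d(np.asarray(self.center, dtype=float))
        if scale.shape[0] != scale.shape[1] or scale.shape[0] != center.size:
            raise ValueError("scale must be square and match the center dimension")
        if not np.allclose(scale, scale.T):
            raise ValueError("scale matrix must be symmetric")
        eigmin = np.linalg.eigvalsh(scale).min()
        if eigmin <= 1e-10:
            raise ValueError(
                "scale matrix is (near-)singular; drop constant parameters or "
                "add jitter to the diagonal"
            )
        object.__setattr__(self, "scale", scale)
        object.__setattr__(self, "center", center)

    @classmethod
    def from_draws(
        cls, draws: np.ndarray, df: float | None = None, scale: str = "correlation"
    ) -> "ImportanceDensity":
        draws = np.atleast_2d(draws)
        if draws.ndim != 2:
            raise ValueError("draws must be (c, d)")
        c = draws.shape[0]
        if scale == "correlation":
            mat = np.corrcoef(draws, rowvar=False)
        elif scale == "covariance":
            mat = np.cov(draws, rowvar=False)
        else:
            raise ValueError("scale must be 'correlation' or 'covariance'")
        mat = np.atleast_2d(mat)
        return cls(df=float(df if df is not None else c), center=draws.mean(axis=0), scale=mat)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return multivariate_t.logpdf(
            np.atleast_2d(x), loc=self.center, shape=self.scale, df=self.df
        )


def gd_log_marginal(
    draws: np.ndarray,
    loglik: np.ndarray | Callable[[np.ndarray], float],
    logprior: np.ndarray | Callable[[np.ndarray], float],
    importance: ImportanceDensity | None = None,
    scale: str = "correlation",
) -> tuple[float, float]:
    """Reciprocal-importance-sampling log marginal likelihood.

    Parameters
    ----------
    draws : (c, d) array
        Posterior draws of the (unconstrained) parameter vector. A model
        with no free parameters (d = 0 columns) returns the likelihood
        unchanged.
    loglik, logprior : array of length c, or callable applied per draw
        Log likelihood / log prior (with Jacobians for any transform) at
        each draw.
    importance : optional
        Importance density; defaults to a multivariate t with df = c
        fitted to the draws.

    Returns
    -------
    (log_marginal, mc_standard_error)
        MC standard error is a delete-one jackknife over draws.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    c = draws.shape[0]
    ll = np.asarray([loglik(w) for w in draws] if callable(loglik) else loglik, float)
    lp = np.asarray(
        [logprior(w) for w in draws] if callable(logprior) else logprior, float
    )
    if ll.shape != (c,) or lp.shape != (c,):
        raise ValueError("loglik/logprior must yield one value per draw")
    for name, v in (("loglik", ll), ("logprior", lp)):
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ValueError(f"non-finite {name} at draw {bad}")
    if draws.shape[1] == 0:
        # zero-dimensional model: marginal equals the likelihood exactly
        if np.ptp(ll) > 1e-12:
            raise ValueError("zero-dimensional model must have constant likelihood")
        return float(ll[0]), 0.0
    if importance is None:
        importance = ImportanceDensity.from_draws(draws, scale=scale)
    logf = np.asarray(importance.logpdf(draws), dtype=float).reshape(c)
    if not np.all(np.isfinite(logf)):
        bad = int(np.flatnonzero(~np.isfinite(logf))[0])
        raise ValueError(f"non-finite importance log-density at draw {bad}")

    terms = logf - ll - lp  # log of f / (lik * prior) per draw
    lse = logsumexp(terms)
    logml = -(lse - np.log(c))
    # jackknife: leave-one-out estimates via log(exp(lse) - exp(term_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = -(lse + np.log1p(-np.exp(terms - lse)) - np.log(c - 1))
    ok = np.isfinite(loo)
    if ok.sum() >= 2:
        se = float(np.sqrt((c - 1) / ok.sum() * ((loo[ok] - loo[ok].mean()) ** 2).sum()))
    else:
        se = float("nan")
    return float(logml), se


def scr_log_marginal(
    samples: PosteriorSamples,
    data: CaptureHistory,
    space: StateSpace,
    spec: ModelSpec,
    scale: str = "correlation",
    max_draws: int | None = None,
) -> tuple[float, float]:
    """Gelfand-Dey log marginal likelihood for a fitted SCR model.

    The parameter vector is the model's free top-level parameters (plus
    psi and psi_sex) on unconstrained scales, evaluated against the
    integrated likelihood with all latent state marginalized out.
    ``max_draws`` thins the retained sample evenly to bound cost.
    """
    free = free_parameters(spec, include_mixing=True)
    draws_df = samples.draws
    if max_draws is not None and len(draws_df) > max_draws:
        idx = np.linspace(0, len(draws_df) - 1, max_draws).round().astype(int)
        draws_df = draws_df.iloc[idx]
    natural = draws_df[[f.name for f in free]]
    unconstrained = np.column_stack(
        [
            [f.to_unconstrained(v) for v in natural[f.name]]
            for f in free
        ]
    )
    ll = np.array(
        [
            integrated_loglik(params_from_row(row, spec), data, space, spec)
            for _, row in draws_df.iterrows()
        ]
    )
    lp = np.array(
        [sum(f.logprior(x) for f, x in zip(free, w)) for w in unconstrained]
    )
    return gd_log_marginal(unconstrained, ll, lp, scale=scale)


def compare_models(
    log_marginals: Sequence[float],
    prior_probs: Sequence[float] | None = None,
    reference: int = 0,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Posterior model probabilities, Bayes factors vs a reference model,
    and the log10 / 2-ln transforms of the Bayes factor.

    ``prior_probs`` defaults to a uniform model prior.
    """
    logml = np.asarray(log_marginals, dtype=float)
    n = logml.size
    if prior_probs is None:
        prior = np.full(n, 1.0 / n)
    else:
        prior = np.asarray(prior_probs, dtype=float)
        if prior.shape != (n,):
            raise ValueError("prior_probs length must match log_marginals")
        if not np.isclose(prior.sum(), 1.0):
            raise ValueError("prior_probs must sum to 1")
    if not 0 <= reference < n:
        raise ValueError("reference index out of range")
    log_post = logml + np.log(prior)
    post = np.exp(log_post - logsumexp(log_post))
    delta = logml - logml[reference]
    bayes = np.exp(delta)
    table = pd.DataFrame(
        {
            "log_marginal": logml,
            "prior_prob": prior,
            "posterior_prob": post,
            "bayes_factor": bayes,
            "log10_bf": delta / np.log(10.0),
            "two_ln_bf": 2.0 * delta,
        },
        index=list(names) if names is not None else range(n),
    )
    return table
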