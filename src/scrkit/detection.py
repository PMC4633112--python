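"""Detection kernel and likelihood computations.

The encounter model is a per-occasion Bernoulli with hazard-based
detection probability

    p(d) = 1 - exp(-lam0 * exp(-0.5 * (d / sigma)^(2 * theta)))

where ``theta`` in [0.5, 1] interpolates between an exponential
(theta = 0.5) and a Gaussian / half-normal (theta = 1) distance kernel,
``lam0`` is the baseline encounter hazard at distance zero, and ``sigma``
is the movement scale. The same kernel backs the simulator, the MCMC
sampler and the marginal-likelihood estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import logsumexp

from .data import CaptureHistory, StateSpace, TrapArray

__all__ = [
    "ScrParams",
    "ModelSpec",
    "detection_prob",
    "per_individual_loglik",
    "integrated_loglik",
]

MODEL_NAMES = ("distance", "sex", "sigma-sex", "sex+sigma-sex")


@dataclass(frozen=True)
class ScrParams:
    """Top-level model parameters.

    ``beta_sex`` acts multiplicatively on the log hazard: the male baseline
    hazard is ``lam0_female * exp(beta_sex)``. ``psi`` is the
    data-augmentation inclusion probability and ``psi_sex`` the proportion
    of the (super)population that is male.
    """

    lam0_female: float
    sigma_female: float
    beta_sex: float = 0.0
    sigma_male: float | None = None
    theta: float = 1.0
    psi: float = 0.5
    psi_sex: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_male is None:
            object.__setattr__(self, "sigma_male", self.sigma_female)
        if self.lam0_female <= 0:
            raise ValueError("lam0_female must be > 0")
        if self.sigma_female <= 0 or self.sigma_male <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0.5, 1]")
        if not 0 <= self.psi <= 1 or not 0 <= self.psi_sex <= 1:
            raise ValueError("psi and psi_sex must lie in [0, 1]")

    def lam0(self, sex: str) -> float:
        return self.lam0_female * (np.exp(self.beta_sex) if sex == "M" else 1.0)

    def sigma(self, sex: str) -> float:
        return self.sigma_male if sex == "M" else self.sigma_female


@dataclass(frozen=True)
class PriorSpec:
    """Proper priors for the top-level parameters (required for marginal
    likelihoods). Uniform bounds / normal moments on the natural scale."""

    lam0_max: float = 5.0
    beta_sex_sd: float = 10.0
    sigma_max: float = 20.0
    theta_bounds: tuple[float, float] = (0.5, 1.0)
    # psi, psi_sex ~ Beta(1, 1); with M slots this makes N = sum(z)
    # marginally uniform on {0..M}.


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates are active, plus augmentation size and priors."""

    sex_on_lam0: bool = False
    sex_on_sigma: bool = False
    theta_fixed: float | None = 1.0  # None -> theta is estimated
    M: int = 0
    priors: PriorSpec = field(default_factory=PriorSpec)

    @classmethod
    def from_name(
        cls,
        name: str,
        M: int,
        theta_fixed: float | None = 1.0,
        priors: PriorSpec | None = None,
    ) -> "ModelSpec":
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
        return cls(
            sex_on_lam0=name in ("sex", "sex+sigma-sex"),
            sex_on_sigma=name in ("sigma-sex", "sex+sigma-sex"),
            theta_fixed=theta_fixed,
            M=M,
            priors=priors or PriorSpec(),
        )

    @property
    def name(self) -> str:
        return {
            (False, False): "distance",
            (True, False): "sex",
            (False, True): "sigma-sex",
            (True, True): "sex+sigma-sex",
        }[(self.sex_on_lam0, self.sex_on_sigma)]

    def constrain(self, params: ScrParams) -> ScrParams:
        """Zero out / tie parameters not present in this model."""
        out = params
        if not self.sex_on_lam0:
            out = replace(out, beta_sex=0.0)
        if not self.sex_on_sigma:
            out = replace(out, sigma_male=out.sigma_female)
        if self.theta_fixed is not None:
            out = replace(out, theta=self.theta_fixed)
        return out


def detection_prob(
    d: float | np.ndarray, lam0: float, sigma: float, theta: float = 1.0
) -> float | np.ndarray:
    """Per-occasion detection probability at distance ``d``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if lam0 <= 0 or sigma <= 0:
        raise ValueError("lam0 and sigma must be > 0")
    if not 0.5 <= theta <= 1.0:
        raise ValueError("theta must lie in [0.5, 1]")
    hazard = lam0 * np.exp(-0.5 * (d / sigma) ** (2.0 * theta))
    p = -np.expm1(-hazard)
    return float(p) if p.ndim == 0 else p


def _log_p_matrices(
    d2: np.ndarray, lam0: float, sigma: float, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """log p and log(1-p) for a squared-distance array, computed stably.

    log(1-p) = -hazard exactly; log p uses log(-expm1(-hazard)).
    """
    hazard = lam0 * np.exp(-0.5 * (d2 / sigma**2) ** theta)
    with np.errstate(divide="ignore"):
        logp = np.log(-np.expm1(-hazard))
    return logp, -hazard


def per_individual_loglik(
    y_i: np.ndarray,
    s: np.ndarray,
    sex: str,
    params: ScrParams,
    traps: TrapArray,
) -> float:
    """Bernoulli log-likelihood of one trap x occasion history given an
    activity center ``s``; non-operating trap-occasions contribute nothing.
    """
    y_i = np.asarray(y_i)
    J, K = y_i.shape
    d2 = ((traps.coords - np.asarray(s, dtype=float)) ** 2).sum(axis=1)
    logp, log1mp = _log_p_matrices(
        d2, params.lam0(sex), params.sigma(sex), params.theta
    )
    op = traps.operation if traps.operation is not None else np.ones((J, K))
    return float((op * (y_i * logp[:, None] + (1 - y_i) * log1mp[:, None])).sum())


def _sex_weights(sex: str, psi_sex: float) -> dict[str, float]:
    if sex == "F":
        return {"F": 1.0}
    if sex == "M":
        return {"M": 1.0}
    return {"F": 1.0 - psi_sex, "M": psi_sex}


def integrated_loglik(
    params: ScrParams,
    data: CaptureHistory,
    space: StateSpace,
    spec: ModelSpec,
) -> float:
    """Observation log-likelihood with all latent state marginalized.

    For each of the M augmented slots, the activity center is summed over
    statespace pixels (uniform weight), sex over {F, M} with weights
    (1-psi_sex, psi_sex) where unknown, and the inclusion indicator over
    {in, out}. Slots are exchangeable: no N-choose-n multiplicity term is
    included, a convention shared by all models so Bayes factors are
    unaffected.
    """
    params = spec.constrain(params)
    n_obs = data.n_individuals
    if spec.M < n_obs:
        raise ValueError("spec.M must be >= number of observed individuals")
    K = data.calendar.n_occasions
    counts = data.counts_by_trap()  # (n, J)
    k_eff = data.traps.effective_occasions(K)  # (J,)
    d2 = (
        (space.pixel_centers[:, None, :] - data.traps.coords[None, :, :]) ** 2
    ).sum(axis=2)  # (P, J)
    P = space.n_pixels

    log_pix: dict[str, np.ndarray] = {}
    log_zero: dict[str, np.ndarray] = {}
    for sex in ("F", "M"):
        logp, log1mp = _log_p_matrices(
            d2, params.lam0(sex), params.sigma(sex), params.theta
        )
        # (n, P): log-lik of each observed history at each pixel
        log_pix[sex] = counts @ logp.T + (k_eff - counts) @ log1mp.T
        # (P,): log-lik of an all-zero history at each pixel
        log_zero[sex] = log1mp @ k_eff

    log_psi = np.log(params.psi) if params.psi > 0 else -np.inf
    log_unif = -np.log(P)

    total = 0.0
    for i in range(n_obs):
        weights = _sex_weights(data.sex[i], params.psi_sex)
        terms = [
            np.log(w) + logsumexp(log_pix[sex][i]) + log_unif
            for sex, w in weights.items()
            if w > 0
        ]
        total += log_psi + logsumexp(terms)

    n_aug = spec.M - n_obs
    if n_aug:
        weights = _sex_weights("U", params.psi_sex)
        zero_terms = [
            np.log(w) + logsumexp(log_zero[sex]) + log_unif
            for sex, w in weights.items()
            if w > 0
        ]
        log_in = log_psi + logsumexp(zero_terms)
        log_out = np.log1p(-params.psi) if params.psi < 1 else -np.inf
        total += n_aug * np.logaddexp(log_in, log_out)
    return float(total)
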