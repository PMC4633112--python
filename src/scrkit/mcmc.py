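"""Data-augmentation MCMC sampler for spatial capture-recapture models.

The latent state comprises, for each of M augmented slots, an inclusion
indicator z, a statespace pixel s and (where unknown) a sex label.
Top-level parameters move by random-walk Metropolis on unconstrained
scales; z, sex, psi and psi_sex have conjugate/Bernoulli full-conditional
Gibbs updates, and activity centers are refreshed by a full categorical
scan over pixels. Proposal scales are tuned to a 25-45% acceptance rate
during burn-in only, so detailed balance holds for every retained draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import CaptureHistory, StateSpace
from .detection import ModelSpec, PriorSpec, ScrParams, _log_p_matrices

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "DensitySummary",
    "FreeParameter",
    "free_parameters",
    "fit",
    "summarize",
    "density_surface",
]


@dataclass(frozen=True)
class McmcConfig:
    iterations: int = 20_000
    burnin: int = 5_000
    thin: int = 2
    seed: int = 0
    tune: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("need 0 <= burnin < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass(frozen=True)
class DensitySummary:
    """Equal-tailed posterior summary with standardized 95% CI width."""

    median: float
    lower95: float
    upper95: float

    @property
    def sw(self) -> float:
        """(upper - lower) / median; dimensionless precision measure."""
        if self.median == 0:
            return float("nan") if self.upper95 != self.lower95 else 0.0
        return (self.upper95 - self.lower95) / self.median


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus latent-state summaries and run metadata."""

    draws: pd.DataFrame  # one row per retained draw, one column per quantity
    occupancy: np.ndarray  # (c, P) active-center counts per pixel
    meta: dict

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def n_active(self) -> np.ndarray:
        return self.draws["N"].to_numpy()


# ---------------------------------------------------------------------------
# Free-parameter definitions shared with the marginal-likelihood estimator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreeParameter:
    """A scalar parameter with its unconstrained transform and prior.

    ``logprior`` is evaluated on the unconstrained scale and includes the
    Jacobian of the transform, so Metropolis ratios and the Gelfand-Dey
    estimator can work directly with unconstrained vectors.
    """

    name: str
    to_unconstrained: Callable[[float], float]
    to_natural: Callable[[float], float]
    logprior: Callable[[float], float]


def _log_uniform_param(name: str, upper: float) -> FreeParameter:
    # natural ~ Uniform(0, upper), sampled as x = log(natural)
    log_upper = np.log(upper)

    def logprior(x: float) -> float:
        return x - log_upper if x < log_upper else -np.inf

    return FreeParameter(name, np.log, np.exp, logprior)


def _logit_interval_param(name: str, lo: float, hi: float) -> FreeParameter:
    # natural ~ Uniform(lo, hi), sampled as x = logit((natural-lo)/(hi-lo))
    def to_u(v: float) -> float:
        return float(logit((v - lo) / (hi - lo)))

    def to_n(x: float) -> float:
        return lo + (hi - lo) * float(expit(x))

    def logprior(x: float) -> float:
        # uniform density 1/(hi-lo) times Jacobian (hi-lo)*sig*(1-sig)
        return float(-np.logaddexp(0, x) - np.logaddexp(0, -x))

    return FreeParameter(name, to_u, to_n, logprior)


def _normal_param(name: str, sd: float) -> FreeParameter:
    def logprior(x: float) -> float:
        return float(-0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi))

    return FreeParameter(name, lambda v: v, lambda x: x, logprior)


def free_parameters(spec: ModelSpec, include_mixing: bool = True) -> list[FreeParameter]:
    """Unconstrained parameterization of a model's free parameters.

    ``include_mixing`` adds psi and psi_sex (Beta(1,1) priors on the natural
    scale), which are Gibbs-updated during sampling but belong to the
    parameter vector used for marginal likelihoods.
    """
    pri: PriorSpec = spec.priors
    out = [_log_uniform_param("lam0_female", pri.lam0_max)]
    if spec.sex_on_lam0:
        out.append(_normal_param("beta_sex", pri.beta_sex_sd))
    out.append(_log_uniform_param("sigma_female", pri.sigma_max))
    if spec.sex_on_sigma:
        out.append(_log_uniform_param("sigma_male", pri.sigma_max))
    if spec.theta_fixed is None:
        out.append(_logit_interval_param("theta", *pri.theta_bounds))
    if include_mixing:
        out.append(_logit_interval_param("psi", 0.0, 1.0))
        out.append(_logit_interval_param("psi_sex", 0.0, 1.0))
    return out


def sample_prior(spec: ModelSpec, n: int, seed: int = 0) -> pd.DataFrame:
    """Independent draws of the free parameters from their priors
    (natural scale); backs prior-recovery and prior-predictive checks."""
    rng = np.random.default_rng(seed)
    pri = spec.priors
    out = {"lam0_female": rng.uniform(0.0, pri.lam0_max, n)}
    if spec.sex_on_lam0:
        out["beta_sex"] = rng.normal(0.0, pri.beta_sex_sd, n)
    out["sigma_female"] = rng.uniform(0.0, pri.sigma_max, n)
    if spec.sex_on_sigma:
        out["sigma_male"] = rng.uniform(0.0, pri.sigma_max, n)
    if spec.theta_fixed is None:
        out["theta"] = rng.uniform(*pri.theta_bounds, n)
    out["psi"] = rng.beta(1.0, 1.0, n)
    out["psi_sex"] = rng.beta(1.0, 1.0, n)
    return pd.DataFrame(out)


def params_from_row(row: dict | pd.Series, spec: ModelSpec) -> ScrParams:
    """Rebuild an ScrParams from a draws-table row, honoring the spec."""
    return spec.constrain(
        ScrParams(
            lam0_female=float(row["lam0_female"]),
            beta_sex=float(row.get("beta_sex", 0.0)),
            sigma_female=float(row["sigma_female"]),
            sigma_male=float(row.get("sigma_male", row["sigma_female"])),
            theta=float(row.get("theta", spec.theta_fixed or 1.0)),
            psi=float(row.get("psi", 0.5)),
            psi_sex=float(row.get("psi_sex", 0.5)),
        )
    )


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------


class _State:
    """Mutable sampler state for one chain."""

    def __init__(
        self,
        data: CaptureHistory,
        space: StateSpace,
        spec: ModelSpec,
        rng: np.random.Generator,
    ):
        self.spec = spec
        self.rng = rng
        self.P = space.n_pixels
        K = data.calendar.n_occasions
        self.k_eff = data.traps.effective_occasions(K).astype(float)
        n_obs = data.n_individuals
        self.n_obs = n_obs
        self.M = spec.M
        counts = data.counts_by_trap().astype(float)  # (n_obs, J)
        self.counts = counts
        self.d2 = (
            (space.pixel_centers[:, None, :] - data.traps.coords[None, :, :]) ** 2
        ).sum(axis=2)  # (P, J)
        # sex: 0 female, 1 male; fixed where observed and labeled
        self.sex = np.zeros(self.M, dtype=np.int8)
        self.sex_fixed = np.zeros(self.M, dtype=bool)
        for i, lab in enumerate(data.sex):
            if lab in ("F", "M"):
                self.sex[i] = 1 if lab == "M" else 0
                self.sex_fixed[i] = True
        self.sex[~self.sex_fixed] = rng.integers(0, 2, (~self.sex_fixed).sum())
        self.z = np.zeros(self.M, dtype=bool)
        self.z[:n_obs] = True
        self.z[n_obs:] = rng.uniform(size=self.M - n_obs) < 0.5
        # data-driven starting values
        centroid = np.array(
            [
                (counts[i][:, None] * data.traps.coords).sum(0) / counts[i].sum()
                for i in range(n_obs)
            ]
        )
        self.s = rng.integers(0, self.P, self.M)
        if n_obs:
            self.s[:n_obs] = np.argmin(
                ((space.pixel_centers[None] - centroid[:, None]) ** 2).sum(2), axis=1
            )
        lam0_init = max(1e-3, counts.sum() / (max(n_obs, 1) * K * counts.shape[1]) * 10)
        sigma_init = max(space.spacing, 0.1 * (space.extent[1] - space.extent[0]))
        self.params = spec.constrain(
            ScrParams(
                lam0_female=min(lam0_init, spec.priors.lam0_max * 0.5),
                sigma_female=min(sigma_init, spec.priors.sigma_max * 0.5),
                beta_sex=0.0,
                sigma_male=min(sigma_init, spec.priors.sigma_max * 0.5),
                theta=spec.theta_fixed if spec.theta_fixed is not None else 0.75,
                psi=max(0.1, min(0.9, 2 * n_obs / self.M)),
                psi_sex=0.5,
            )
        )
        self.free = free_parameters(spec, include_mixing=False)
        self.x = np.array(
            [f.to_unconstrained(getattr(self.params, f.name)) for f in self.free]
        )
        self.kernels = self._compute_kernels(self.params)

    # -- likelihood machinery ------------------------------------------------

    def _compute_kernels(self, params: ScrParams) -> dict:
        """logp/log1mp (P, J) per sex plus all-zero-history pixel scores."""
        out = {}
        for code, lab in ((0, "F"), (1, "M")):
            logp, log1mp = _log_p_matrices(
                self.d2, params.lam0(lab), params.sigma(lab), params.theta
            )
            out[code] = (logp, log1mp, log1mp @ self.k_eff)
        return out

    def loglik(self, kernels: dict | None = None) -> float:
        """Joint log-likelihood of all active slots at their current pixels."""
        kern = self.kernels if kernels is None else kernels
        total = 0.0
        for code in (0, 1):
            logp, log1mp, zero = kern[code]
            rows = np.flatnonzero(self.z[: self.n_obs] & (self.sex[: self.n_obs] == code))
            if rows.size:
                lp = logp[self.s[rows]]
                l1p = log1mp[self.s[rows]]
                c = self.counts[rows]
                total += (c * lp).sum() + ((self.k_eff - c) * l1p).sum()
            aug = np.flatnonzero(self.z[self.n_obs :] & (self.sex[self.n_obs :] == code))
            if aug.size:
                total += zero[self.s[self.n_obs + aug]].sum()
        return float(total)

    # -- updates -------------------------------------------------------------

    def update_parameters(self, prop_sd: np.ndarray, accept: np.ndarray) -> None:
        ll = self.loglik()
        for idx, fp in enumerate(self.free):
            x_new = self.x.copy()
            x_new[idx] += self.rng.normal(0.0, prop_sd[idx])
            lp_new = fp.logprior(x_new[idx])
            if not np.isfinite(lp_new):
                continue
            params_new = self._params_from_x(x_new)
            kern_new = self._compute_kernels(params_new)
            ll_new = self.loglik(kern_new)
            log_ratio = ll_new + lp_new - ll - fp.logprior(self.x[idx])
            if np.log(self.rng.uniform()) < log_ratio:
                self.x = x_new
                self.params = params_new
                self.kernels = kern_new
                ll = ll_new
                accept[idx] += 1

    def _params_from_x(self, x: np.ndarray) -> ScrParams:
        vals = {f.name: f.to_natural(xi) for f, xi in zip(self.free, x)}
        return self.spec.constrain(
            ScrParams(
                lam0_female=vals["lam0_female"],
                beta_sex=vals.get("beta_sex", 0.0),
                sigma_female=vals["sigma_female"],
                sigma_male=vals.get("sigma_male", vals["sigma_female"]),
                theta=vals.get(
                    "theta",
                    self.spec.theta_fixed if self.spec.theta_fixed is not None else 1.0,
                ),
                psi=self.params.psi,
                psi_sex=self.params.psi_sex,
            )
        )

    def update_centers(self) -> None:
        """Full categorical scan over pixels (Gumbel-max sampling)."""
        for code in (0, 1):
            logp, log1mp, zero = self.kernels[code]
            rows = np.flatnonzero(self.z[: self.n_obs] & (self.sex[: self.n_obs] == code))
            if rows.size:
                c = self.counts[rows]
                scores = c @ logp.T + (self.k_eff - c) @ log1mp.T  # (m, P)
                gumbel = -np.log(-np.log(self.rng.uniform(size=scores.shape)))
                self.s[rows] = np.argmax(scores + gumbel, axis=1)
            aug = self.n_obs + np.flatnonzero(
                self.z[self.n_obs :] & (self.sex[self.n_obs :] == code)
            )
            if aug.size:
                w = np.exp(zero - zero.max())
                self.s[aug] = self.rng.choice(self.P, size=aug.size, p=w / w.sum())
        inactive = np.flatnonzero(~self.z)
        if inactive.size:
            self.s[inactive] = self.rng.integers(0, self.P, inactive.size)

    def update_z(self) -> None:
        aug = np.arange(self.n_obs, self.M)
        if not aug.size:
            return
        zero_scores = np.where(
            self.sex[aug] == 0,
            self.kernels[0][2][self.s[aug]],
            self.kernels[1][2][self.s[aug]],
        )
        psi = self.params.psi
        logit_p = np.log(psi) - np.log1p(-psi) + zero_scores
        self.z[aug] = self.rng.uniform(size=aug.size) < expit(logit_p)

    def update_sex(self) -> None:
        rows = np.flatnonzero(~self.sex_fixed)
        if not rows.size:
            return
        ps = self.params.psi_sex
        logit_m = np.full(rows.size, np.log(ps) - np.log1p(-ps))
        active = self.z[rows]
        act = rows[active]
        if act.size:
            s_act = self.s[act]
            ll_f = np.empty(act.size)
            ll_m = np.empty(act.size)
            obs = act < self.n_obs
            for code, buf in ((0, ll_f), (1, ll_m)):
                logp, log1mp, zero = self.kernels[code]
                if obs.any():
                    c = self.counts[act[obs]]
                    buf[obs] = (c * logp[s_act[obs]]).sum(1) + (
                        (self.k_eff - c) * log1mp[s_act[obs]]
                    ).sum(1)
                if (~obs).any():
                    buf[~obs] = zero[s_act[~obs]]
            logit_m[active] += ll_m - ll_f
        self.sex[rows] = self.rng.uniform(size=rows.size) < expit(logit_m)

    def update_mixing(self) -> None:
        n_in = int(self.z.sum())
        psi = self.rng.beta(1 + n_in, 1 + self.M - n_in)
        n_male = int(self.sex.sum())
        psi_sex = self.rng.beta(1 + n_male, 1 + self.M - n_male)
        from dataclasses import replace

        self.params = replace(self.params, psi=psi, psi_sex=psi_sex)


def fit(
    data: CaptureHistory,
    space: StateSpace,
    spec: ModelSpec,
    config: McmcConfig,
) -> PosteriorSamples:
    """Run one chain and return retained, thinned posterior draws.

    Raises on zero-capture data; warns (and flags ``meta``) when the
    posterior population size presses against the augmentation limit M.
    """
    if data.n_individuals == 0 or data.n_detections == 0:
        raise ValueError("cannot fit a model to data with zero captures")
    if spec.M <= data.n_individuals:
        raise ValueError("spec.M must exceed the number of observed individuals")
    rng = np.random.default_rng(config.seed)
    state = _State(data, space, spec, rng)
    n_free = len(state.free)
    prop_sd = np.full(n_free, 0.2)
    accept = np.zeros(n_free)
    tune_window = 50

    records: list[dict] = []
    occupancy = np.zeros((config.n_draws, space.n_pixels), dtype=np.uint16)
    kept = 0
    for it in range(config.iterations):
        state.update_parameters(prop_sd, accept)
        state.update_centers()
        state.update_z()
        state.update_sex()
        state.update_mixing()
        if config.tune and it < config.burnin and (it + 1) % tune_window == 0:
            rate = accept / tune_window
            prop_sd *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))
            prop_sd = np.clip(prop_sd, 1e-3, 5.0)
            accept[:] = 0
        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            p = state.params
            n_active = int(state.z.sum())
            records.append(
                {
                    "lam0_female": p.lam0_female,
                    "beta_sex": p.beta_sex,
                    "sigma_female": p.sigma_female,
                    "sigma_male": p.sigma_male,
                    "theta": p.theta,
                    "psi": p.psi,
                    "psi_sex": p.psi_sex,
                    "N": n_active,
                    "density": n_active / space.total_area,
                }
            )
            occupancy[kept] = np.bincount(
                state.s[state.z], minlength=space.n_pixels
            ).astype(np.uint16)
            kept += 1

    draws = pd.DataFrame(records)
    meta = {
        "model": spec.name,
        "M": spec.M,
        "iterations": config.iterations,
        "burnin": config.burnin,
        "thin": config.thin,
        "seed": config.seed,
        "n_draws": kept,
        "total_area": space.total_area,
        "augmentation_warning": bool((draws["N"] >= 0.9 * spec.M).any()),
        "diagnostics": _diagnostics(draws, spec),
    }
    if meta["augmentation_warning"]:
        warnings.warn(
            "posterior population size approached the augmentation limit M; "
            "refit with a larger M",
            stacklevel=2,
        )
    return PosteriorSamples(draws=draws, occupancy=occupancy[:kept], meta=meta)


def _diagnostics(draws: pd.DataFrame, spec: ModelSpec) -> dict:
    """Effective sample size and split-chain R-hat per free parameter."""
    try:
        import arviz as az
    except ImportError:  # pragma: no cover
        return {}
    import logging

    logging.getLogger("arviz").setLevel(logging.ERROR)
    names = [f.name for f in free_parameters(spec)] + ["N"]
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in names:
            if name not in draws or draws[name].nunique() <= 1:
                continue
            v = draws[name].to_numpy()
            half = len(v) // 2
            if half < 4:
                continue
            arr = np.stack([v[:half], v[half : 2 * half]])  # split-chain view
            ess = float(az.ess(az.convert_to_dataset(arr))["x"])
            rhat = float(az.rhat(az.convert_to_dataset(arr))["x"])
            out[name] = {"ess": ess, "rhat": rhat, "rhat_warn": rhat > 1.1}
    return out


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def summarize(samples: PosteriorSamples, params: list[str] | None = None) -> pd.DataFrame:
    """Median, equal-tailed 95% bounds and standardized width per column."""
    if samples.n_draws < 100:
        warnings.warn("fewer than 100 draws; summaries will be noisy", stacklevel=2)
    cols = params or [c for c in samples.draws.columns]
    rows = {}
    for col in cols:
        v = samples.draws[col].to_numpy()
        summ = DensitySummary(
            median=float(np.median(v)),
            lower95=float(np.percentile(v, 2.5)),
            upper95=float(np.percentile(v, 97.5)),
        )
        rows[col] = {
            "median": summ.median,
            "lower95": summ.lower95,
            "upper95": summ.upper95,
            "sw": summ.sw,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def density_summary(samples: PosteriorSamples) -> DensitySummary:
    v = samples.draws["density"].to_numpy()
    return DensitySummary(
        median=float(np.median(v)),
        lower95=float(np.percentile(v, 2.5)),
        upper95=float(np.percentile(v, 97.5)),
    )


def density_surface(
    samples: PosteriorSamples,
    space: StateSpace,
    region: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Per-pixel posterior mean density plus a region abundance summary.

    ``region`` is an optional boolean pixel mask; abundance is the per-draw
    count of active centers inside it (whole statespace by default).
    """
    if region is None:
        region = np.ones(space.n_pixels, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if region.shape != (space.n_pixels,):
        raise ValueError("region mask must have one entry per pixel")
    surface = samples.occupancy.mean(axis=0) / space.pixel_area
    abundance = samples.occupancy[:, region].sum(axis=1)
    summary = pd.Series(
        {
            "median": float(np.median(abundance)),
            "lower95": float(np.percentile(abundance, 2.5)),
            "upper95": float(np.percentile(abundance, 97.5)),
            "mean": float(abundance.mean()),
        }
    )
    return surface, summary
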