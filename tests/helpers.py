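"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's own likelihood code paths: the
emission probability is rebuilt from first principles and the latent state
is enumerated exhaustively.
"""

import itertools
import math

import numpy as np


def bernoulli_emission(y_i, center, sex, params, trap_coords, operation=None):
    """Product of per-cell Bernoulli masses, computed cell by cell."""
    J, K = y_i.shape
    prob = 1.0
    for j in range(J):
        d = math.dist(center, trap_coords[j])
        lam0 = params.lam0_female * (
            math.exp(params.beta_sex) if sex == "M" else 1.0
        )
        sigma = params.sigma_male if sex == "M" else params.sigma_female
        p = 1.0 - math.exp(-lam0 * math.exp(-0.5 * (d / sigma) ** (2 * params.theta)))
        for k in range(K):
            if operation is not None and not operation[j, k]:
                continue
            prob *= p if y_i[j, k] else (1.0 - p)
    return prob


def brute_force_integrated_lik(params, histories, sexes, M, pixels, trap_coords):
    """Marginal likelihood by full enumeration of the joint latent state.

    Enumerates every joint assignment of (z, pixel, sex) across all M
    slots (observed histories first, all-zero slots after), multiplying
    per-slot prior weights and emissions. Exponential in M and only
    feasible for toy instances.
    """
    n_obs = len(histories)
    J = trap_coords.shape[0]
    K = histories[0].shape[1] if n_obs else 1
    zero_history = np.zeros((J, K), dtype=int)
    P = len(pixels)

    def slot_configs(i):
        if i < n_obs:
            y_i, sex_obs = histories[i], sexes[i]
        else:
            y_i, sex_obs = zero_history, "U"
        for z in (0, 1):
            for pix in range(P):
                for sex in ("F", "M"):
                    if sex_obs in ("F", "M") and sex != sex_obs:
                        continue
                    w = (params.psi if z else 1.0 - params.psi) / P
                    if sex_obs == "U":
                        w *= params.psi_sex if sex == "M" else 1.0 - params.psi_sex
                    if z:
                        emit = bernoulli_emission(
                            y_i, pixels[pix], sex, params, trap_coords
                        )
                    else:
                        emit = 1.0 if not y_i.any() else 0.0
                    yield w * emit

    total = 0.0
    for combo in itertools.product(*(list(slot_configs(i)) for i in range(M))):
        total += math.prod(combo)
    return total
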