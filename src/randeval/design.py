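"""Design computations for a two-arm continuous-endpoint trial.

Effect size, exact non-central-t sample size and power, the probability of a
given terminal imbalance under complete randomization, and estimation of the
selection-bias effect from patient-level data of a previous unmasked trial.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .bias import selection_bias_tau
from .sequences import AllocationSequence

__all__ = [
    "pooled_effect_size",
    "power_two_sample_t",
    "sample_size_two_sample_t",
    "cr_imbalance_probability",
    "estimate_bias_effects",
    "EstimationError",
]


class EstimationError(RuntimeError):
    """The bias-effect regression is not estimable for the given data."""


def pooled_effect_size(mean_e: float, mean_c: float, sd_pooled: float) -> float:
    """Standardized effect size |mean_E - mean_C| / sd_pooled (Cohen's d)."""
    if sd_pooled <= 0:
        raise ValueError("sd_pooled must be > 0")
    return abs(mean_e - mean_c) / sd_pooled


def power_two_sample_t(n_e: int, n_c: int, effect_size: float, alpha: float = 0.05) -> float:
    """Exact two-sided power of the pooled-variance two-sample t test.

    Uses the singly non-central t with non-centrality
    ``delta = d * sqrt(n_E n_C / (n_E + n_C))``.
    """
    if n_e < 2 or n_c < 2:
        raise ValueError("both group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n_e + n_c - 2
    delta = effect_size * np.sqrt(n_e * n_c / (n_e + n_c))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta))


def sample_size_two_sample_t(
    effect_size: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Smallest per-group n with two-sided two-sample t power >= ``power``.

    Starts from the normal-approximation solution and iterates the exact
    non-central-t power up or down to the smallest sufficient n.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    n = max(2, int(np.ceil(2.0 * ((z_a + z_b) / effect_size) ** 2)))
    if power_two_sample_t(n, n, effect_size, alpha) >= power:
        while n > 2 and power_two_sample_t(n - 1, n - 1, effect_size, alpha) >= power:
            n -= 1
    else:
        while power_two_sample_t(n, n, effect_size, alpha) < power:
            n += 1
            if n > 10_000_000:
                raise ValueError("required sample size exceeds 1e7 per group")
    return n


def cr_imbalance_probability(n: int, d_min: int) -> float:
    """P(|N_E - N_C| >= d_min) at the end of a CR trial, exact binomial.

    Under complete randomization ``N_E ~ Binomial(N, 1/2)`` and the terminal
    imbalance is ``|2 N_E - N|``. ``d_min`` is an absolute patient-count
    difference (an "imbalance of 25%" at N = 50 may be read as d_min = 13
    patients difference, or as one arm holding >= 62.5% of patients).
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    if d_min <= 0:
        return 1.0
    # |2k - n| >= d  <=>  k >= (n + d)/2  or  k <= (n - d)/2
    hi = int(np.ceil((n + d_min) / 2.0))
    lo = int(np.floor((n - d_min) / 2.0))
    upper = stats.binom.sf(hi - 1, n, 0.5)
    lower = stats.binom.cdf(lo, n, 0.5)
    return float(min(upper + lower, 1.0))


def estimate_bias_effects(responses, seq) -> tuple[float, float, float]:
    """Estimate (eta_hat, sigma_hat, gamma_hat) from a completed unmasked trial.

    Fits the two-way main-effects linear model

        y_i = mu_C + (mu_E - mu_C) * T_i + eta * s_i + eps_i,

    where ``s_i = sign(N_E(i-1) - N_C(i-1))`` is the convergence-strategy
    guessing covariate, by least squares. ``sigma_hat`` is the residual
    standard deviation (residual degrees of freedom N - 3) and
    ``gamma_hat = eta_hat / sigma_hat`` the standardized selection effect.

    Raises
    ------
    EstimationError
        If the guessing covariate is collinear with the design (e.g. constant
        along the whole sequence), so eta is not identifiable.
    """
    if isinstance(seq, AllocationSequence):
        t = seq.assignments.astype(float)
    else:
        t = AllocationSequence(seq).assignments.astype(float)
    y = np.asarray(responses, dtype=float)
    if y.shape != t.shape:
        raise ValueError("responses must have the same length as the sequence")
    n = t.size
    if t.sum() in (0, n):
        raise EstimationError("both arms must be non-empty")
    s = np.sign(selection_bias_tau(t.astype(int), eta=1.0, q=0.5))
    design = np.column_stack([np.ones(n), t, s])
    rank = np.linalg.matrix_rank(design)
    if rank < 3:
        raise EstimationError(
            "guessing covariate s_i is collinear with the design; "
            "the selection effect eta is not identifiable for this sequence"
        )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - 3
    if dof < 1:
        raise EstimationError("too few observations to estimate the residual variance")
    sigma_hat = float(np.sqrt(resid @ resid / dof))
    eta_hat = float(coef[2])
    gamma_hat = eta_hat / sigma_hat if sigma_hat > 0 else float("nan")
    return eta_hat, sigma_hat, gamma_hat
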