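"""Bias models for the patient responses of a two-arm trial.

The response of patient ``i`` is modelled as

    y_i = mu_E * T_i + mu_C * (1 - T_i) + tau_i + eps_i,    eps_i ~ N(0, sigma^2)

where ``tau_i`` is a fixed, unobserved bias shift. Two mechanisms for ``tau``
are implemented, separately and combined additively:

Selection bias (convergence strategy)
    An unmasked recruiter guesses the upcoming assignment from the allocation
    history and preferentially enrolls patients with an expected response
    shifted by ``eta`` in the guessed direction. With guessing threshold
    ``q = 1/2`` the shift is ``eta * sign(N_E(i-1) - N_C(i-1))``; for
    ``q > 1/2`` the recruiter only acts when the fraction of remaining
    experimental allocations crosses the threshold, which requires a procedure
    with a fixed terminal split.

Chronological bias (time trend)
    A systematic drift of the expected response across enrollment positions:
    linear (``theta * i/N``), stepwise (``theta`` from a changepoint onward) or
    logarithmic (``theta * log(i)/log(N)``). All three shapes are normalized
    so their maximum equals ``theta``, keeping the effect size comparable
    across shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sequences import AllocationSequence

__all__ = [
    "BiasModel",
    "TREND_KINDS",
    "selection_bias_tau",
    "time_trend_tau",
    "joint_tau",
]

TREND_KINDS = ("none", "linear", "stepwise", "logarithmic")


@dataclass(frozen=True)
class BiasModel:
    """Joint additive bias model: selection bias plus a time trend.

    Parameters
    ----------
    eta
        Selection bias effect (response units, >= 0): the shift in expected
        response of a preferentially enrolled patient.
    q
        Guessing threshold in [1/2, 1]. ``q = 0.5`` is the sign-of-imbalance
        convergence strategy (the worst case); larger ``q`` requires the
        fraction of remaining allocations to one arm to exceed ``q`` before
        the recruiter acts, and needs a procedure with a fixed terminal split.
    trend_kind
        One of ``none``, ``linear``, ``stepwise``, ``logarithmic``.
    theta
        Time-trend effect (response units, >= 0): the maximum drift reached
        at the end of enrollment.
    changepoint
        Enrollment position at which the stepwise trend jumps (required for
        ``stepwise`` only).
    sigma
        Residual standard deviation of the responses (> 0).
    """

    eta: float = 0.0
    q: float = 0.5
    trend_kind: str = "none"
    theta: float = 0.0
    changepoint: Optional[int] = None
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.5 <= self.q <= 1.0:
            raise ValueError("q must lie in [0.5, 1]")
        if self.trend_kind not in TREND_KINDS:
            raise ValueError(f"trend_kind must be one of {TREND_KINDS}")
        if self.trend_kind == "stepwise" and self.changepoint is None:
            raise ValueError("stepwise trend requires a changepoint")

    @property
    def gamma(self) -> float:
        """Standardized selection effect eta / sigma."""
        return self.eta / self.sigma


def _as_assignments(seq) -> np.ndarray:
    if isinstance(seq, AllocationSequence):
        return seq.assignments
    if isinstance(seq, str):
        return AllocationSequence.from_labels(seq).assignments
    return AllocationSequence(seq).assignments


def selection_bias_tau(
    seq,
    eta: float,
    q: float = 0.5,
    terminal_target: Optional[int] = None,
) -> np.ndarray:
    """Selection-bias shifts tau_i for one allocation sequence.

    For ``q = 0.5`` (convergence strategy):

        tau_i = eta * sign(N_E(i-1) - N_C(i-1)).

    For ``q > 0.5`` the recruiter acts only on confident guesses: with
    ``p_E(i-1) = (N_E_target - N_E(i-1)) / (N - (i-1))`` the fraction of
    remaining allocations to E,

        tau_i = eta * ( 1{p_E(i-1) <= 1-q} - 1{p_E(i-1) >= q} ),

    which reduces exactly to the sign rule at q = 0.5 (the two indicators
    cancel at p_E = 1/2). This form requires a known terminal count
    ``terminal_target`` = N_E (e.g. N/2 for a balance-forcing procedure).

    Parameters
    ----------
    seq
        Allocation sequence (AllocationSequence, 0/1 vector or 'E'/'C' string).
    eta
        Selection bias effect (response units).
    q
        Guessing threshold in [0.5, 1].
    terminal_target
        Fixed final number of experimental-arm patients; required when
        ``q > 0.5``.
    """
    t = _as_assignments(seq)
    n = t.size
    if not 0.5 <= q <= 1.0:
        raise ValueError("q must lie in [0.5, 1]")
    ne_before = np.concatenate(([0], np.cumsum(t)[:-1]))
    if q == 0.5:
        d_before = 2 * ne_before - np.arange(n)
        return eta * np.sign(d_before).astype(float)
    if terminal_target is None:
        raise ValueError("q > 0.5 requires a terminal target N_E (fixed final split)")
    remaining = n - np.arange(n)
    p_e = (terminal_target - ne_before) / remaining
    return eta * ((p_e <= 1.0 - q).astype(float) - (p_e >= q).astype(float))


def time_trend_tau(
    n: int,
    theta: float,
    trend_kind: str = "linear",
    changepoint: Optional[int] = None,
) -> np.ndarray:
    """Chronological-bias shifts tau_i for enrollment positions 1..N.

    linear:       tau_i = theta * i / N
    stepwise:     tau_i = theta * 1{i >= changepoint}
    logarithmic:  tau_i = theta * log(i) / log(N)   (tau_1 = 0, tau_N = theta)
    none:         tau_i = 0
    """
    if n < 1:
        raise ValueError("N must be >= 1")
    if trend_kind not in TREND_KINDS:
        raise ValueError(f"trend_kind must be one of {TREND_KINDS}")
    i = np.arange(1, n + 1, dtype=float)
    if trend_kind == "none" or theta == 0.0:
        return np.zeros(n)
    if trend_kind == "linear":
        return theta * i / n
    if trend_kind == "stepwise":
        if changepoint is None:
            raise ValueError("stepwise trend requires a changepoint")
        return theta * (i >= changepoint).astype(float)
    # logarithmic; degenerate N=1 has no scale
    if n == 1:
        return np.zeros(1)
    return theta * np.log(i) / np.log(n)


def joint_tau(seq, model: BiasModel, terminal_target: Optional[int] = None) -> np.ndarray:
    """Additive combination of the time-trend and selection-bias shifts.

    With the sign-rule policy (q = 0.5) and a linear trend this is

        tau_i = theta * i/N + eta * sign(N_E(i-1) - N_C(i-1)).
    """
    t = _as_assignments(seq)
    n = t.size
    trend = time_trend_tau(n, model.theta, model.trend_kind, model.changepoint)
    selection = selection_bias_tau(t, model.eta, model.q, terminal_target)
    return trend + selection
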