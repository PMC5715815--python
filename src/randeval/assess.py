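"""Assessment of randomization procedures by their type-I error distribution.

For a procedure, a sample size and a bias model, every allocation sequence T
has an exact two-sided type-I error probability omega(T) of the nominal
level-alpha t test, computed from the doubly non-central t distribution. A
procedure is summarized by the distribution of omega over its sequences:

* ``mean_omega`` — the expected type-I error probability, and
* ``p_le_alpha`` — the probability that a sequence keeps the level,
  P(omega <= alpha); higher is better.

Two evaluation modes are provided: Monte Carlo over ``r`` sequences drawn from
the procedure (the default; sequences drawn independently, with replacement in
sequence space) and exact summation over all positive-probability sequences,
weighted by their probabilities (small N only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bias import BiasModel, selection_bias_tau, time_trend_tau
from .nct import noncentrality_batch, rejection_probabilities
from .procedures import ProcedureSpec, enumerate_sequences, generate_sequences
from .sequences import AllocationSequence, as_matrix

__all__ = [
    "AssessmentSummary",
    "SimulationConfig",
    "assess_procedure",
    "assess_exact",
    "metric_p_le",
    "sensitivity_analysis",
    "simulate_rejection_rate",
    "sequence_omegas",
    "BOUNDARY_TOL",
]

#: tolerance for the boundary of the omega <= alpha comparison, so the
#: analytically exact no-bias case (omega = alpha) counts as level-preserving
#: despite floating-point noise
BOUNDARY_TOL = 1e-9

_QUANTILE_LEVELS = (0.0, 0.05, 0.25, 0.50, 0.75, 0.95, 1.0)
_QUANTILE_NAMES = ("min", "q05", "q25", "median", "q75", "q95", "max")


@dataclass(frozen=True)
class SimulationConfig:
    """Response-level simulation settings (validation oracle)."""

    mu_e: float = 0.0
    mu_c: float = 0.0
    sigma: float = 1.0
    n_sim: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class AssessmentSummary:
    """Distributional summary of the per-sequence type-I error omega."""

    procedure: ProcedureSpec
    n: int
    bias: BiasModel
    alpha: float
    mode: str  # "monte_carlo" | "exact"
    r: int  # sequences drawn (MC) or enumerated (exact)
    seed: Optional[int]
    mean_omega: float
    p_le_alpha: float
    quantiles: dict[str, float]
    mean_omega_se: Optional[float] = None
    p_le_alpha_se: Optional[float] = None
    n_degenerate: int = 0
    eta: float = field(init=False)
    theta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "eta", self.bias.eta)
        object.__setattr__(self, "theta", self.bias.theta)

    def to_row(self) -> dict:
        """Flat dict for tabular export (CSV / report tables)."""
        row = {
            "procedure": self.procedure.label,
            "N": self.n,
            "eta": self.bias.eta,
            "theta": self.bias.theta,
            "trend": self.bias.trend_kind,
            "sigma": self.bias.sigma,
            "alpha": self.alpha,
            "mode": self.mode,
            "r": self.r,
            "seed": self.seed if self.seed is not None else "",
            "mean_type_one_error": round(self.mean_omega, 6),
            "p_le_alpha": round(self.p_le_alpha, 6),
            "mean_se": round(self.mean_omega_se, 8) if self.mean_omega_se is not None else "",
            "p_le_alpha_se": (
                round(self.p_le_alpha_se, 8) if self.p_le_alpha_se is not None else ""
            ),
            "n_degenerate": self.n_degenerate,
        }
        row.update({f"omega_{k}": round(v, 6) for k, v in self.quantiles.items()})
        return row


def _terminal_target(spec: ProcedureSpec, n: int, q: float) -> Optional[int]:
    """Fixed terminal N_E when the threshold policy (q > 0.5) needs one."""
    if q == 0.5:
        return None
    if spec.name in ("RAR", "PBR") or (spec.name == "MP" and spec.mp_terminal_balance):
        return n // 2
    raise ValueError(
        f"selection-bias threshold q={q} > 0.5 requires a procedure with a "
        f"fixed terminal split; {spec.label} does not force terminal balance"
    )


def _tau_matrix(t_matrix: np.ndarray, bias: BiasModel, terminal_target: Optional[int]) -> np.ndarray:
    """Bias vectors for each sequence row (vectorized over rows)."""
    r, n = t_matrix.shape
    trend = time_trend_tau(n, bias.theta, bias.trend_kind, bias.changepoint)
    if bias.eta == 0.0:
        return np.broadcast_to(trend, (r, n))
    ne_before = np.concatenate(
        [np.zeros((r, 1), dtype=np.int64), np.cumsum(t_matrix, axis=1, dtype=np.int64)[:, :-1]],
        axis=1,
    )
    if bias.q == 0.5:
        d_before = 2 * ne_before - np.arange(n)
        selection = bias.eta * np.sign(d_before)
    else:
        remaining = n - np.arange(n)
        p_e = (terminal_target - ne_before) / remaining
        selection = bias.eta * (
            (p_e <= 1.0 - bias.q).astype(float) - (p_e >= bias.q).astype(float)
        )
    return trend + selection


def sequence_omegas(
    t_matrix: np.ndarray, bias: BiasModel, alpha: float, terminal_target: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence exact type-I error omega for an (r, N) allocation matrix.

    Returns ``(omega, degenerate)``. Sequences with an empty arm (possible
    under complete randomization) have an undefined t statistic; by convention
    their omega is 0 (the test never rejects) and they are flagged.
    """
    tau = _tau_matrix(t_matrix, bias, terminal_target)
    delta, lam, degenerate = noncentrality_batch(t_matrix, tau, bias.sigma, mu_diff=0.0)
    n = t_matrix.shape[1]
    omega = rejection_probabilities(delta, lam, df=n - 2, alpha=alpha)
    omega = np.where(degenerate, 0.0, omega)
    return omega, degenerate


def _weighted_quantiles(values: np.ndarray, weights: np.ndarray) -> dict[str, float]:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    out = {}
    for name, level in zip(_QUANTILE_NAMES, _QUANTILE_LEVELS):
        idx = int(np.searchsorted(cw, level, side="left"))
        out[name] = float(v[min(idx, v.size - 1)])
    return out


def metric_p_le(
    omegas: np.ndarray,
    alpha: float,
    tol: float = BOUNDARY_TOL,
    weights: Optional[np.ndarray] = None,
) -> float:
    """P(omega <= alpha): the share of sequences preserving the test level.

    Boundary inclusion via ``tol`` so omega = alpha counts as preserving.
    With ``weights`` (exact mode) returns the probability-weighted mass.
    """
    omegas = np.asarray(omegas, dtype=float)
    if omegas.size == 0:
        raise ValueError("omegas must be non-empty")
    keep = omegas <= alpha + tol
    if weights is None:
        return float(keep.mean())
    weights = np.asarray(weights, dtype=float)
    return float(weights[keep].sum() / weights.sum())


def assess_procedure(
    spec: ProcedureSpec,
    n: int,
    bias: BiasModel,
    alpha: float = 0.05,
    r: int = 100_000,
    seed: int = 0,
) -> AssessmentSummary:
    """Monte-Carlo assessment: draw ``r`` sequences, evaluate omega for each.

    The reported standard errors are the empirical SE of the mean and the
    binomial SE ``sqrt(p(1-p)/r)`` of ``p_le_alpha``. Deterministic given the
    seed.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    rng = np.random.default_rng(seed)
    target = _terminal_target(spec, n, bias.q)
    t_matrix = generate_sequences(spec, n, r, rng)
    omega, degenerate = sequence_omegas(t_matrix, bias, alpha, target)
    p = metric_p_le(omega, alpha)
    return AssessmentSummary(
        procedure=spec,
        n=n,
        bias=bias,
        alpha=alpha,
        mode="monte_carlo",
        r=r,
        seed=seed,
        mean_omega=float(omega.mean()),
        p_le_alpha=p,
        quantiles=_weighted_quantiles(omega, np.full(r, 1.0 / r)),
        mean_omega_se=float(omega.std(ddof=1) / np.sqrt(r)) if r > 1 else None,
        p_le_alpha_se=float(np.sqrt(p * (1.0 - p) / r)),
        n_degenerate=int(degenerate.sum()),
    )


def assess_exact(
    spec: ProcedureSpec,
    n: int,
    bias: BiasModel,
    alpha: float = 0.05,
    enumeration_limit: int = 20,
) -> AssessmentSummary:
    """Exact assessment: sum omega over all positive-probability sequences.

    The expectation and P(omega <= alpha) are weighted by the exact sequence
    probabilities — required for procedures whose sequences are not
    equiprobable (EBC, UD, BSD, CHEN).
    """
    pairs = enumerate_sequences(spec, n, limit=enumeration_limit)
    t_matrix = as_matrix([s for s, _ in pairs])
    probs = np.array([p for _, p in pairs])
    target = _terminal_target(spec, n, bias.q)
    omega, degenerate = sequence_omegas(t_matrix, bias, alpha, target)
    mean_omega = float(np.dot(probs, omega))
    p = metric_p_le(omega, alpha, weights=probs)
    return AssessmentSummary(
        procedure=spec,
        n=n,
        bias=bias,
        alpha=alpha,
        mode="exact",
        r=len(pairs),
        seed=None,
        mean_omega=mean_omega,
        p_le_alpha=p,
        quantiles=_weighted_quantiles(omega, probs),
        n_degenerate=int(degenerate.sum()),
    )


def sensitivity_analysis(
    spec: ProcedureSpec,
    n: int,
    eta_values,
    theta_values,
    sigma: float,
    alpha: float = 0.05,
    r: int = 100_000,
    seed: int = 0,
    trend_kind: str = "linear",
    q: float = 0.5,
    changepoint: Optional[int] = None,
    paired: bool = False,
) -> list[AssessmentSummary]:
    """Assessment over a grid of (eta, theta) bias-strength values.

    With ``paired=False`` (default) the full cross product of
    ``eta_values x theta_values`` is evaluated, ordered by (eta, theta); with
    ``paired=True`` the two lists are zipped (e.g. the proportional "50%
    change" cells (0.04, 0.13), (0.09, 0.26), (0.14, 0.39)).

    Every cell uses the same base seed, so cells differ only in the bias
    parameters (not in Monte-Carlo noise) and a 1x1 grid reproduces
    :func:`assess_procedure` exactly.
    """
    eta_values = list(eta_values)
    theta_values = list(theta_values)
    if not eta_values or not theta_values:
        raise ValueError("eta_values and theta_values must be non-empty")
    if paired:
        if len(eta_values) != len(theta_values):
            raise ValueError("paired grids require equal-length eta and theta lists")
        cells = list(zip(eta_values, theta_values))
    else:
        cells = [(e, t) for e in eta_values for t in theta_values]
    out = []
    for eta, theta in cells:
        bias = BiasModel(
            eta=eta, q=q, trend_kind=trend_kind, theta=theta,
            changepoint=changepoint, sigma=sigma,
        )
        out.append(assess_procedure(spec, n, bias, alpha=alpha, r=r, seed=seed))
    return out


def simulate_rejection_rate(
    seq,
    tau,
    sim: SimulationConfig,
    alpha: float = 0.05,
) -> float:
    """Empirical two-sided rejection rate of the pooled-variance t test.

    Simulates ``n_sim`` response vectors from the model
    ``y_i = mu_E T_i + mu_C (1 - T_i) + tau_i + eps_i`` and applies the
    two-sample t test at level ``alpha``. Monte-Carlo oracle for
    :func:`randeval.nct.rejection_probability`.
    """
    from scipy import stats

    if isinstance(seq, AllocationSequence):
        t = seq.assignments.astype(float)
    else:
        t = AllocationSequence(seq).assignments.astype(float)
    tau = np.asarray(tau, dtype=float)
    n = t.size
    n_e = int(t.sum())
    n_c = n - n_e
    if n_e == 0 or n_c == 0:
        from .nct import DegenerateDesignError

        raise DegenerateDesignError("sequence allocates every patient to one arm")
    rng = np.random.default_rng(sim.seed)
    mu = sim.mu_e * t + sim.mu_c * (1.0 - t) + tau
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    mask_e = t == 1.0
    rejected = 0
    # simulate in blocks to bound memory at large n_sim
    block = max(1, min(sim.n_sim, 200_000))
    done = 0
    while done < sim.n_sim:
        m = min(block, sim.n_sim - done)
        y = mu + rng.normal(0.0, sim.sigma, size=(m, n))
        ybar_e = y[:, mask_e].mean(axis=1)
        ybar_c = y[:, ~mask_e].mean(axis=1)
        ss = ((y[:, mask_e] - ybar_e[:, None]) ** 2).sum(axis=1) + (
            (y[:, ~mask_e] - ybar_c[:, None]) ** 2
        ).sum(axis=1)
        s_pooled = np.sqrt(ss / (n - 2))
        stat = np.sqrt(n_e * n_c / n) * (ybar_e - ybar_c) / s_pooled
        rejected += int((np.abs(stat) > t_crit).sum())
        done += m
    return rejected / sim.n_sim
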