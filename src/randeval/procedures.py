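"""Restricted randomization procedures for two-arm 1:1 trials.

Eight classical procedures are implemented, spanning the spectrum from fully
unrestricted to strictly balance-forcing:

* ``CR`` — complete randomization (fair coin).
* ``EBC(p)`` — Efron's biased coin: probability ``p`` toward the
  under-represented arm, fair coin at equality.
* ``UD(alpha, beta)`` — Wei's urn design: adaptively biased coin with
  allocation probability ``(alpha + beta*N_C(i-1)) / (2*alpha + beta*(i-1))``.
* ``BSD(a)`` — big stick design: fair coin with a forced deterministic
  assignment whenever the running imbalance reaches the maximum tolerated
  imbalance (MTI) ``a``.
* ``CHEN(a, p)`` — Chen's design: Efron's biased coin with an MTI ``a``.
* ``MP(a)`` — Berger's maximal procedure: uniform distribution over all
  sequences respecting MTI ``a`` (and, in the classical variant, terminal
  balance), sampled exactly via dynamic-programming path counts.
* ``RAR`` — random allocation rule: uniform over all balanced sequences.
* ``PBR(b)`` — permuted block randomization: RAR within successive blocks of
  size ``b``.

All conditional allocation probabilities depend on the enrollment position and
the number of prior experimental-arm assignments only, which the vectorized
sampler exploits to generate large Monte-Carlo batches of sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .sequences import AllocationSequence

__all__ = [
    "ProcedureSpec",
    "ConfigurationError",
    "FeasibilityError",
    "EnumerationLimitError",
    "next_allocation_prob",
    "generate_sequence",
    "generate_sequences",
    "sequence_probability",
    "enumerate_sequences",
    "imbalance_bound",
    "PROCEDURE_NAMES",
]

PROCEDURE_NAMES = ("CR", "RAR", "PBR", "BSD", "MP", "EBC", "CHEN", "UD")

DEFAULT_ENUMERATION_LIMIT = 20


class ConfigurationError(ValueError):
    """Invalid procedure parameters or an incompatible (procedure, N) pair."""


class FeasibilityError(ValueError):
    """An allocation prefix that has probability zero under the procedure."""


class EnumerationLimitError(RuntimeError):
    """Requested exhaustive enumeration beyond the configured size guard."""


@dataclass(frozen=True)
class ProcedureSpec:
    """A named randomization procedure with its parameters.

    Only the parameters required by the named procedure may be set; all others
    must be left as ``None``. Use the class-method constructors
    (:meth:`cr`, :meth:`pbr`, ...) in application code.
    """

    name: str
    block_size: Optional[int] = None
    mti: Optional[int] = None
    coin_prob: Optional[float] = None
    urn_init: Optional[int] = None
    urn_add: Optional[int] = None
    mp_terminal_balance: bool = True

    def __post_init__(self) -> None:
        if self.name not in PROCEDURE_NAMES:
            raise ConfigurationError(
                f"unknown procedure {self.name!r}; expected one of {PROCEDURE_NAMES}"
            )
        required = {
            "CR": (),
            "RAR": (),
            "PBR": ("block_size",),
            "BSD": ("mti",),
            "MP": ("mti",),
            "EBC": ("coin_prob",),
            "CHEN": ("mti", "coin_prob"),
            "UD": ("urn_init", "urn_add"),
        }[self.name]
        params = {
            "block_size": self.block_size,
            "mti": self.mti,
            "coin_prob": self.coin_prob,
            "urn_init": self.urn_init,
            "urn_add": self.urn_add,
        }
        for key, value in params.items():
            if key in required and value is None:
                raise ConfigurationError(f"{self.name} requires parameter {key!r}")
            if key not in required and value is not None:
                raise ConfigurationError(f"{self.name} does not take parameter {key!r}")
        if self.block_size is not None:
            if self.block_size < 2 or self.block_size % 2:
                raise ConfigurationError("block_size must be a positive even integer")
        if self.mti is not None and self.mti < 1:
            raise ConfigurationError("mti must be a positive integer")
        if self.coin_prob is not None and not 0.5 <= self.coin_prob <= 1.0:
            raise ConfigurationError("coin_prob must lie in [0.5, 1]")
        if self.urn_init is not None and (self.urn_init < 0 or self.urn_add < 0):
            raise ConfigurationError("urn parameters must be non-negative integers")

    # -- constructors ------------------------------------------------------

    @classmethod
    def cr(cls) -> "ProcedureSpec":
        return cls("CR")

    @classmethod
    def rar(cls) -> "ProcedureSpec":
        return cls("RAR")

    @classmethod
    def pbr(cls, block_size: int) -> "ProcedureSpec":
        return cls("PBR", block_size=int(block_size))

    @classmethod
    def bsd(cls, mti: int) -> "ProcedureSpec":
        return cls("BSD", mti=int(mti))

    @classmethod
    def mp(cls, mti: int, terminal_balance: bool = True) -> "ProcedureSpec":
        return cls("MP", mti=int(mti), mp_terminal_balance=bool(terminal_balance))

    @classmethod
    def ebc(cls, coin_prob: float) -> "ProcedureSpec":
        return cls("EBC", coin_prob=float(coin_prob))

    @classmethod
    def chen(cls, mti: int, coin_prob: float) -> "ProcedureSpec":
        return cls("CHEN", mti=int(mti), coin_prob=float(coin_prob))

    @classmethod
    def ud(cls, urn_init: int, urn_add: int) -> "ProcedureSpec":
        return cls("UD", urn_init=int(urn_init), urn_add=int(urn_add))

    @classmethod
    def from_params(cls, name: str, **params) -> "ProcedureSpec":
        """Build from a name plus short parameter keys as used by the CLI.

        Recognized keys: ``b`` (block size), ``a`` (MTI), ``p`` (coin
        probability), ``alpha``/``beta`` (urn), ``terminal_balance``.
        """
        name = name.upper()
        alias = {
            "b": "block_size",
            "a": "mti",
            "p": "coin_prob",
            "alpha": "urn_init",
            "beta": "urn_add",
            "terminal_balance": "mp_terminal_balance",
        }
        kwargs = {}
        for key, value in params.items():
            field = alias.get(key, key)
            if field == "mp_terminal_balance":
                value = str(value).lower() in ("1", "true", "yes")
            elif field == "coin_prob":
                value = float(value)
            else:
                value = int(value)
            kwargs[field] = value
        return cls(name, **kwargs)

    # -- presentation ------------------------------------------------------

    @property
    def label(self) -> str:
        """Conventional display label, e.g. ``PBR(2)`` or ``CHEN(2, 0.67)``."""
        if self.name in ("CR", "RAR"):
            return self.name
        if self.name == "PBR":
            return f"PBR({self.block_size})"
        if self.name == "BSD":
            return f"BSD({self.mti})"
        if self.name == "MP":
            return f"MP({self.mti})"
        if self.name == "EBC":
            return f"EBC({self.coin_prob:.2g})"
        if self.name == "CHEN":
            return f"CHEN({self.mti}, {self.coin_prob:.2g})"
        return f"UD({self.urn_init},{self.urn_add})"

    def validate_n(self, n: int) -> None:
        """Check that the procedure can allocate exactly ``n`` patients."""
        if n < 1:
            raise ConfigurationError("N must be a positive integer")
        if self.name in ("RAR",) and n % 2:
            raise ConfigurationError(f"{self.label} requires even N (terminal balance)")
        if self.name == "MP" and self.mp_terminal_balance and n % 2:
            raise ConfigurationError(
                "MP with terminal balance requires even N"
            )
        if self.name == "PBR" and n % self.block_size:
            raise ConfigurationError(
                f"N={n} is not divisible by the block size b={self.block_size}"
            )


# ---------------------------------------------------------------------------
# maximal procedure: dynamic-programming path counts
# ---------------------------------------------------------------------------


def _mp_suffix_counts(n: int, a: int, terminal_balance: bool) -> list[dict[int, int]]:
    """Exact counts of admissible completions for the maximal procedure.

    ``counts[i][d]`` is the number of length-``n - i`` suffixes that keep the
    running imbalance within ``[-a, a]`` at every position (and end at 0 when
    ``terminal_balance``) starting from imbalance ``d`` after ``i``
    assignments. Python integers keep the counts exact at any N.
    """
    counts: list[dict[int, int]] = [dict() for _ in range(n + 1)]
    for d in range(-a, a + 1):
        counts[n][d] = 0 if (terminal_balance and d != 0) else 1
    for i in range(n - 1, -1, -1):
        for d in range(-a, a + 1):
            total = 0
            if d + 1 <= a:
                total += counts[i + 1][d + 1]
            if d - 1 >= -a:
                total += counts[i + 1][d - 1]
            counts[i][d] = total
    return counts


class _MpTable:
    """Cached per-(N, a, terminal_balance) conditional probability table."""

    _cache: dict[tuple[int, int, bool], "_MpTable"] = {}

    def __init__(self, n: int, a: int, terminal_balance: bool) -> None:
        self.counts = _mp_suffix_counts(n, a, terminal_balance)
        # prob_e[i, d + a] = P(T_{i+1} = 1 | imbalance d after i assignments)
        prob = np.zeros((n, 2 * a + 1))
        for i in range(n):
            for d in range(-a, a + 1):
                total = self.counts[i][d]
                if total == 0:
                    continue
                up = self.counts[i + 1][d + 1] if d + 1 <= a else 0
                prob[i, d + a] = up / total
        self.prob_e = prob
        self.a = a

    @classmethod
    def get(cls, n: int, a: int, terminal_balance: bool) -> "_MpTable":
        key = (n, a, terminal_balance)
        if key not in cls._cache:
            cls._cache[key] = cls(n, a, terminal_balance)
        return cls._cache[key]


# ---------------------------------------------------------------------------
# conditional allocation probabilities
# ---------------------------------------------------------------------------


def _probs_e(spec: ProcedureSpec, n: int, i1: int, ne: np.ndarray) -> np.ndarray:
    """P(T_i = 1) vectorized over the state ``ne`` = N_E(i-1); ``i1`` = i-1."""
    ne = np.asarray(ne, dtype=np.int64)
    d = 2 * ne - i1
    name = spec.name
    if name == "CR":
        return np.full(ne.shape, 0.5)
    if name == "EBC":
        p = spec.coin_prob
        return np.where(d == 0, 0.5, np.where(d < 0, p, 1.0 - p))
    if name == "BSD":
        a = spec.mti
        return np.where(d <= -a, 1.0, np.where(d >= a, 0.0, 0.5))
    if name == "CHEN":
        a, p = spec.mti, spec.coin_prob
        inner = np.where(d == 0, 0.5, np.where(d < 0, p, 1.0 - p))
        return np.where(d <= -a, 1.0, np.where(d >= a, 0.0, inner))
    if name == "UD":
        alpha, beta = spec.urn_init, spec.urn_add
        denom = 2 * alpha + beta * i1
        if denom == 0:
            return np.full(ne.shape, 0.5)
        nc = i1 - ne
        return (alpha + beta * nc) / denom
    if name == "RAR":
        return (n / 2 - ne) / (n - i1)
    if name == "PBR":
        b = spec.block_size
        j = i1 % b
        nb = ne - (i1 // b) * (b // 2)  # completed blocks are balanced
        return (b / 2 - nb) / (b - j)
    if name == "MP":
        table = _MpTable.get(n, spec.mti, spec.mp_terminal_balance)
        return table.prob_e[i1, d + spec.mti]
    raise ConfigurationError(f"unknown procedure {name!r}")  # pragma: no cover


def _check_prefix_feasible(spec: ProcedureSpec, n: int, i1: int, ne: int) -> None:
    d = 2 * ne - i1
    if spec.name == "RAR" and (ne > n / 2 or (i1 - ne) > n / 2):
        raise FeasibilityError(f"RAR prefix with N_E={ne}, N_C={i1 - ne} exceeds N/2={n / 2:g}")
    if spec.name == "PBR":
        b = spec.block_size
        nb = ne - (i1 // b) * (b // 2)
        jb = i1 % b
        if not (0 <= nb <= b / 2 and 0 <= jb - nb <= b / 2):
            raise FeasibilityError("PBR prefix violates within-block balance")
    if spec.name in ("BSD", "CHEN") and abs(d) > spec.mti:
        raise FeasibilityError(f"|D|={abs(d)} exceeds the MTI a={spec.mti}")
    if spec.name == "MP":
        a = spec.mti
        if abs(d) > a:
            raise FeasibilityError(f"|D|={abs(d)} exceeds the MTI a={a}")
        table = _MpTable.get(n, a, spec.mp_terminal_balance)
        if table.counts[i1][d] == 0:
            raise FeasibilityError("MP prefix admits no admissible completion")


def _prefix_state(history) -> tuple[int, int]:
    if isinstance(history, AllocationSequence):
        arr = history.assignments
    else:
        arr = np.asarray(list(history), dtype=np.int64)
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("history must contain only 0 (C) and 1 (E)")
    return int(arr.size), int(arr.sum())


def next_allocation_prob(spec: ProcedureSpec, history, n: int) -> float:
    """P(T_i = 1 | allocation history) for the next patient.

    Parameters
    ----------
    spec
        The randomization procedure.
    history
        The allocations already made (prefix of length i-1); an
        :class:`AllocationSequence`, a 0/1 iterable, or an ``'E'/'C'`` string.
    n
        Total planned sample size N.

    Raises
    ------
    FeasibilityError
        If the prefix has probability zero under the procedure.
    """
    if isinstance(history, str):
        history = AllocationSequence.from_labels(history) if history else []
    i1, ne = _prefix_state(history)
    if i1 >= n:
        raise ValueError(f"history of length {i1} leaves no allocation to make (N={n})")
    spec.validate_n(n)
    _check_prefix_feasible(spec, n, i1, ne)
    return float(_probs_e(spec, n, i1, np.asarray([ne]))[0])


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------


def generate_sequences(
    spec: ProcedureSpec, n: int, r: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``r`` independent allocation sequences as an ``(r, n)`` 0/1 matrix.

    One uniform variate is consumed per patient per sequence, in enrollment
    order, so streams are reproducible across procedures for a given seed.
    """
    spec.validate_n(n)
    if r < 1:
        raise ConfigurationError("r must be >= 1")
    u = rng.random((r, n))
    out = np.zeros((r, n), dtype=np.int8)
    ne = np.zeros(r, dtype=np.int64)
    for i1 in range(n):
        p = _probs_e(spec, n, i1, ne)
        t = (u[:, i1] < p).astype(np.int8)
        out[:, i1] = t
        ne += t
    return out


def generate_sequence(spec: ProcedureSpec, n: int, rng: np.random.Generator) -> AllocationSequence:
    """Draw one allocation sequence."""
    return AllocationSequence(generate_sequences(spec, n, 1, rng)[0])


# ---------------------------------------------------------------------------
# exact probabilities
# ---------------------------------------------------------------------------


def sequence_probability(spec: ProcedureSpec, seq) -> float:
    """Probability of a complete allocation sequence under the procedure.

    The product of the conditional allocation probabilities; 0 for sequences
    the procedure cannot produce.
    """
    if isinstance(seq, str):
        seq = AllocationSequence.from_labels(seq)
    elif not isinstance(seq, AllocationSequence):
        seq = AllocationSequence(seq)
    n = seq.n
    spec.validate_n(n)
    ne_before, _ = seq.counts_before()
    prob = 1.0
    for i1 in range(n):
        try:
            _check_prefix_feasible(spec, n, i1, int(ne_before[i1]))
        except FeasibilityError:
            return 0.0
        p_e = float(_probs_e(spec, n, i1, ne_before[i1 : i1 + 1])[0])
        step = p_e if seq.assignments[i1] else 1.0 - p_e
        if step == 0.0:
            return 0.0
        prob *= step
    return prob


def enumerate_sequences(
    spec: ProcedureSpec, n: int, limit: int = DEFAULT_ENUMERATION_LIMIT
) -> list[tuple[AllocationSequence, float]]:
    """All sequences with positive probability, with their exact probabilities.

    Depth-first traversal of the allocation tree, pruning zero-probability
    branches; probabilities over the returned set sum to 1.

    Raises
    ------
    EnumerationLimitError
        If ``n`` exceeds ``limit`` (guard against 2^n blow-up).
    """
    spec.validate_n(n)
    if n > limit:
        raise EnumerationLimitError(
            f"N={n} exceeds the enumeration limit {limit}; raise `limit` explicitly"
        )
    results: list[tuple[AllocationSequence, float]] = []
    prefix = np.zeros(n, dtype=np.int8)

    def dfs(i1: int, ne: int, prob: float) -> None:
        if i1 == n:
            results.append((AllocationSequence(prefix.copy()), prob))
            return
        p_e = float(_probs_e(spec, n, i1, np.asarray([ne]))[0])
        if p_e > 0.0:
            prefix[i1] = 1
            dfs(i1 + 1, ne + 1, prob * p_e)
        if p_e < 1.0:
            prefix[i1] = 0
            dfs(i1 + 1, ne, prob * (1.0 - p_e))

    dfs(0, 0, 1.0)
    return results


def imbalance_bound(spec: ProcedureSpec, n: int) -> int:
    """Largest |D(i)| attainable at any point under the procedure.

    Used to rank procedures by strength of imbalance control (smaller is
    stricter).
    """
    if spec.name in ("BSD", "CHEN", "MP"):
        return int(spec.mti)
    if spec.name == "RAR":
        return n // 2
    if spec.name == "PBR":
        return spec.block_size // 2
    return n  # CR, EBC, UD: no hard bound
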