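"""Configuration for a full evaluation run (YAML-backed).

A config bundles the trial parameters, the candidate procedures, the bias
model, the evaluation settings and optional sensitivity grids; everything is
validated up front, before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .bias import BiasModel
from .procedures import ProcedureSpec

__all__ = ["EvaluationConfig", "load_config"]


@dataclass(frozen=True)
class EvaluationConfig:
    """Validated parameters of an evaluation run."""

    n: int
    alpha: float
    procedures: tuple[ProcedureSpec, ...]
    bias: BiasModel
    r: int = 100_000
    seed: int = 0
    exact: bool = False
    enumeration_limit: int = 20
    eta_values: tuple[float, ...] = ()
    theta_values: tuple[float, ...] = ()
    sensitivity_paired: bool = True
    title: str = "Evaluation of randomization procedures"
    output_path: str = "report.md"
    fmt: str = "markdown"
    allocation: str = "1:1"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("trial.N must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("trial.alpha must lie in (0, 1)")
        if self.allocation != "1:1":
            raise ValueError("only 1:1 allocation is supported")
        if not self.procedures:
            raise ValueError("at least one procedure is required")
        if not self.exact and self.seed is None:
            raise ValueError("a seed is mandatory for Monte-Carlo runs")
        if self.r < 1:
            raise ValueError("evaluation.r must be >= 1")
        if self.fmt != "markdown":
            raise ValueError("only markdown reports are supported")
        for spec in self.procedures:
            spec.validate_n(self.n)

    @property
    def has_sensitivity(self) -> bool:
        return len(self.eta_values) > 1 or len(self.theta_values) > 1


def _parse_procedure(entry) -> ProcedureSpec:
    if isinstance(entry, str):
        return ProcedureSpec.from_params(entry)
    entry = dict(entry)
    name = entry.pop("name")
    return ProcedureSpec.from_params(name, **entry)


def load_config(path) -> EvaluationConfig:
    """Load and validate a YAML configuration file.

    Expected keys: ``trial`` (N, alpha, allocation), ``procedures`` (list of
    name + parameters), ``bias`` (eta, q, trend, theta, changepoint, sigma),
    ``evaluation`` (r, seed, exact, enumeration_limit), optional
    ``sensitivity`` (eta_values, theta_values, paired) and ``report``
    (title, output_path, format).
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    trial = raw.get("trial", {})
    bias_raw = dict(raw.get("bias", {}))
    evaluation = raw.get("evaluation", {})
    sensitivity = raw.get("sensitivity", {}) or {}
    report = raw.get("report", {}) or {}
    bias = BiasModel(
        eta=float(bias_raw.get("eta", 0.0)),
        q=float(bias_raw.get("q", 0.5)),
        trend_kind=str(bias_raw.get("trend", "none")),
        theta=float(bias_raw.get("theta", 0.0)),
        changepoint=bias_raw.get("changepoint"),
        sigma=float(bias_raw.get("sigma", 1.0)),
    )
    return EvaluationConfig(
        n=int(trial["N"]),
        alpha=float(trial.get("alpha", 0.05)),
        allocation=str(trial.get("allocation", "1:1")),
        procedures=tuple(_parse_procedure(p) for p in raw.get("procedures", [])),
        bias=bias,
        r=int(evaluation.get("r", 100_000)),
        seed=int(evaluation.get("seed", 0)),
        exact=bool(evaluation.get("exact", False)),
        enumeration_limit=int(evaluation.get("enumeration_limit", 20)),
        eta_values=tuple(float(x) for x in sensitivity.get("eta_values", ())),
        theta_values=tuple(float(x) for x in sensitivity.get("theta_values", ())),
        sensitivity_paired=bool(sensitivity.get("paired", True)),
        title=str(report.get("title", "Evaluation of randomization procedures")),
        output_path=str(report.get("output_path", "report.md")),
        fmt=str(report.get("format", "markdown")),
    )
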