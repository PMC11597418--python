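"""Model-performance metrics (RMSE, Nash–Sutcliffe efficiency E, index of
agreement d) and trial-and-error calibration.

Calibration mirrors the manual tune-run-compare loop as a deterministic
coordinate descent on successively refined grids: each round sweeps every
parameter over a grid inside its current bracket, keeps the best value, and
shrinks the bracket around it.  The objective is the mean over observation
series of RMSE normalized by the observed standard deviation, so series in
different units contribute comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalMetrics",
    "CalibSpec",
    "CalibrationResult",
    "rmse",
    "nse",
    "agreement_index",
    "evaluate",
    "calibrate",
]

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Undefined metric or invalid calibration setup."""


def _paired(obs, sim) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float)
    p = np.asarray(sim, dtype=float)
    if o.shape != p.shape:
        raise EvaluationError("observed and simulated series differ in length")
    if o.size < 1:
        raise EvaluationError("empty series")
    return o, p


def rmse(obs, sim) -> float:
    """Root mean squared error √(Σ(O−P)²/n)."""
    o, p = _paired(obs, sim)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def nse(obs, sim) -> float:
    """Nash–Sutcliffe efficiency 1 − Σ(O−P)²/Σ(O−O̅)²; 1 is perfect, 0
    matches the mean predictor.  Undefined for constant observations."""
    o, p = _paired(obs, sim)
    denom = float(np.sum((o - o.mean()) ** 2))
    if denom == 0:
        raise EvaluationError("constant observations: Nash-Sutcliffe undefined")
    return float(1.0 - np.sum((o - p) ** 2) / denom)


def agreement_index(obs, sim) -> float:
    """Index of agreement d = 1 − Σ(O−P)²/Σ(|P−O̅|+|O−O̅|)² ∈ [0, 1].

    The bound holds mathematically (the denominator dominates the numerator
    by the triangle inequality); the result is clipped to [0, 1] to absorb
    last-ulp rounding."""
    o, p = _paired(obs, sim)
    om = o.mean()
    denom = float(np.sum((np.abs(p - om) + np.abs(o - om)) ** 2))
    if denom == 0:
        raise EvaluationError("degenerate series: index of agreement undefined")
    return float(np.clip(1.0 - np.sum((o - p) ** 2) / denom, 0.0, 1.0))


@dataclass(frozen=True)
class EvalMetrics:
    """RMSE (series units), index of agreement d ∈ [0,1], efficiency E ≤ 1."""

    rmse: float
    d: float
    e: float


def evaluate(obs, sim) -> EvalMetrics:
    return EvalMetrics(rmse=rmse(obs, sim), d=agreement_index(obs, sim), e=nse(obs, sim))


@dataclass(frozen=True)
class CalibSpec:
    """Parameter bounds and search settings for coordinate-descent
    calibration.  ``bounds`` maps parameter name → (lower, upper)."""

    bounds: dict[str, tuple[float, float]]
    n_rounds: int = 12
    n_grid: int = 9
    shrink: float = 0.5
    min_width: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bounds:
            raise EvaluationError("no parameters to calibrate")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise EvaluationError(f"invalid bounds for {name}")
        if self.n_grid < 3 or self.n_rounds < 1:
            raise EvaluationError("need n_grid >= 3 and n_rounds >= 1")
        if not (0 < self.shrink < 1):
            raise EvaluationError("shrink must lie in (0, 1)")


@dataclass
class CalibrationResult:
    """Fitted parameters, objective trace (non-increasing), and per-series
    metrics at the optimum."""

    params: dict[str, float]
    objective: float
    trace: list[float] = field(default_factory=list)
    metrics: dict[str, EvalMetrics] = field(default_factory=dict)
    n_evaluations: int = 0


def normalized_rmse_objective(observations: dict[str, tuple], simulate) -> "callable":
    """Build the default objective: mean over series of RMSE / sd(observed).

    ``observations`` maps series name → (obs_values, extractor) where
    ``extractor(sim_output)`` returns the simulated values aligned to the
    observation timestamps; ``simulate(params)`` runs the model.
    """

    sds = {}
    for name, (obs, _) in observations.items():
        sd = float(np.std(np.asarray(obs, dtype=float)))
        sds[name] = sd if sd > 0 else 1.0

    def objective(params: dict[str, float]) -> float:
        out = simulate(params)
        total = 0.0
        for name, (obs, extract) in observations.items():
            total += rmse(obs, extract(out)) / sds[name]
        return total / len(observations)

    return objective


def calibrate(
    spec: CalibSpec,
    objective,
    observations: dict[str, tuple] | None = None,
    simulate=None,
) -> CalibrationResult:
    """Deterministic trial-and-error search: coordinate descent on refined
    grids minimizing ``objective(params)``.

    A failing candidate (objective raises) is rejected and logged, never
    fatal.  If ``observations`` and ``simulate`` are given, per-series RMSE/
    d/E metrics are computed at the optimum.
    """
    params = {k: 0.5 * (lo + hi) for k, (lo, hi) in spec.bounds.items()}
    widths = {k: hi - lo for k, (lo, hi) in spec.bounds.items()}
    n_eval = 0

    def safe(candidate: dict[str, float]) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            return float(objective(candidate))
        except Exception as exc:  # simulator failure on a candidate
            logger.warning("candidate %s rejected: %s", candidate, exc)
            return np.inf

    best = safe(params)
    trace = [best]
    # pattern-search schedule: walk at the current resolution while sweeps
    # still move a parameter (handles correlated-parameter ridges), refine
    # the bracket only when a full sweep stalls
    for _ in range(spec.n_rounds):
        moved = False
        for name in spec.bounds:
            lo0, hi0 = spec.bounds[name]
            half = 0.5 * widths[name]
            lo = max(lo0, params[name] - half)
            hi = min(hi0, params[name] + half)
            for value in np.linspace(lo, hi, spec.n_grid):
                candidate = {**params, name: float(value)}
                score = safe(candidate)
                if score < best:
                    best = score
                    params = candidate
                    moved = True
            trace.append(best)
        if not moved:
            for name in widths:
                widths[name] *= spec.shrink
            if all(
                w <= spec.min_width * (hi - lo)
                for w, (lo, hi) in zip(widths.values(), spec.bounds.values())
            ):
                break
    result = CalibrationResult(
        params=params, objective=best, trace=trace, n_evaluations=n_eval
    )
    if observations is not None and simulate is not None:
        out = simulate(params)
        for name, (obs, extract) in observations.items():
            try:
                result.metrics[name] = evaluate(obs, extract(out))
            except EvaluationError:
                logger.warning("metrics undefined for series %s", name)
    return result
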