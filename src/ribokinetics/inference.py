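"""Constrained minimization of the kinetic distance.

The unknown in-vivo rates are parametrized by barrier shifts
``delta = ln(omega_vivo / omega_vitro)`` for the twelve distinct internal
rates (the association constant is fixed by the diffusion argument, by
default to 54% of its in-vitro value).  The measured overall elongation
rate defines a hypersurface in barrier space; the predicted in-vivo point
is the point of that hypersurface closest to the origin in the
tie-weighted Euclidean metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .elongation import (
    CodonContext,
    mean_accommodation_time,
    overall_elongation_rate,
)
from .kinetic_distance import BarrierShifts, distance, rates_from_shifts
from .rates import INTERNAL_RATE_NAMES, TIE_MULTIPLICITY, RateSet

__all__ = [
    "MinimizationProblem",
    "MinimizationResult",
    "InfeasibleSpeedError",
    "DEFAULT_KON_SCALE",
    "calibrate_processing_rate",
    "deduce_in_vivo_rates",
    "scale_factor_report",
]

logger = logging.getLogger(__name__)

#: Default in-vivo/in-vitro ratio of the association rate constant.  Molecular
#: crowding slows ternary-complex diffusion in the cytosol, reducing the
#: bimolecular association constant to about 54% of its in-vitro value.
DEFAULT_KON_SCALE = 0.54


class InfeasibleSpeedError(ValueError):
    """Raised when the requested overall elongation rate cannot be achieved."""


@dataclass(frozen=True)
class MinimizationProblem:
    """Inputs of one in-vivo rate deduction.

    ``contexts`` carry the in-vivo concentrations and codon usage;
    ``v_target`` is the measured overall elongation rate (aa/s);
    ``kon_in_vivo`` fixes the association constant (defaults to
    ``DEFAULT_KON_SCALE`` times the in-vitro value).  ``fixed_coords`` pins
    coordinates at given shifts; ``bounds`` restricts coordinates to
    intervals.
    """

    in_vitro: RateSet
    contexts: tuple[CodonContext, ...]
    v_target: float
    kon_in_vivo: float | None = None
    fixed_coords: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    starts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_target <= 0:
            raise ValueError(f"v_target must be positive, got {self.v_target}")
        unknown = (set(self.fixed_coords) | set(self.bounds)) - set(INTERNAL_RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown coordinates: {sorted(unknown)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} are not well ordered: ({lo}, {hi})")
        object.__setattr__(self, "contexts", tuple(self.contexts))

    @property
    def effective_kon(self) -> float:
        if self.kon_in_vivo is not None:
            return self.kon_in_vivo
        return DEFAULT_KON_SCALE * self.in_vitro.kon


@dataclass(frozen=True)
class MinimizationResult:
    """Deduced in-vivo rates and minimization diagnostics."""

    delta_min: BarrierShifts
    rates_in_vivo: RateSet
    distance: float
    constraint_residual: float
    scale_factors: dict[str, float]
    boundary_flags: tuple[str, ...]
    multistart_spread: float
    n_converged: int


def calibrate_processing_rate(rates: RateSet, contexts, v_measured: float) -> float:
    """Processing rate that makes the overall elongation rate equal ``v_measured``.

    The accommodation times do not involve the processing rate, so the
    overall rate is strictly increasing in ``omega_proc`` with supremum
    ``1/<t_acc>``; the unique root is found by bracketed monotone root
    finding.  The ``omega_proc`` value carried by ``rates`` is ignored.
    """
    if v_measured <= 0:
        raise ValueError(f"measured overall rate must be positive, got {v_measured}")
    contexts = list(contexts)
    t_acc_mean = mean_accommodation_time(rates, contexts)
    v_sup = 1.0 / t_acc_mean
    if v_measured >= v_sup:
        raise InfeasibleSpeedError(
            f"overall rate {v_measured} aa/s is not achievable: the zero-processing-time "
            f"limit is {v_sup:.6g} aa/s"
        )

    def residual(log_w: float) -> float:
        trial = rates.with_rates(omega_proc=math.exp(log_w))
        return overall_elongation_rate(trial, contexts) - v_measured

    lo, hi = math.log(1e-12), math.log(1e12)
    # expand the bracket if the extreme processing rates do not straddle the root
    while residual(lo) > 0:
        lo -= 10
    while residual(hi) < 0:
        hi += 10
    root = optimize.brentq(residual, lo, hi, xtol=1e-15, rtol=1e-14)
    return math.exp(root)


def _rates_from_vector(problem: MinimizationProblem, free_names: list[str],
                       x: np.ndarray) -> RateSet:
    deltas = dict(problem.fixed_coords)
    deltas.update(zip(free_names, x))
    updates = {n: problem.in_vitro[n] * math.exp(d) for n, d in deltas.items()}
    updates["kon"] = problem.effective_kon
    return problem.in_vitro.with_rates(label="deduced in vivo", **updates)


def deduce_in_vivo_rates(problem: MinimizationProblem) -> MinimizationResult:
    """Deduce in-vivo rates by shortest kinetic distance under the speed constraint.

    Minimizes the tie-weighted squared norm of the barrier shifts subject to
    ``overall_elongation_rate(rates(delta)) = v_target`` using SLSQP from
    multiple seeded starting points, then projects the best solution
    radially onto the constraint hypersurface so that the relative residual
    is at working precision.  Fixed coordinates are honored (and still
    contribute to the reported distance); bound coordinates ending on a
    bound are flagged.
    """
    free_names = [n for n in INTERNAL_RATE_NAMES if n not in problem.fixed_coords]
    if not free_names:
        raise ValueError("no free coordinates left to minimize over")
    weights = np.array([TIE_MULTIPLICITY[n] for n in free_names], float)
    fixed_sq = sum(
        TIE_MULTIPLICITY[n] * d * d for n, d in problem.fixed_coords.items()
    )

    def v_of(x: np.ndarray) -> float:
        return overall_elongation_rate(_rates_from_vector(problem, free_names, x), problem.contexts)

    def constraint(x: np.ndarray) -> float:
        return v_of(x) / problem.v_target - 1.0

    def objective(x: np.ndarray) -> float:
        return float(np.dot(weights, x * x))

    def objective_grad(x: np.ndarray) -> np.ndarray:
        return 2.0 * weights * x

    # Feasibility check along the all-coordinates-equal direction: scaling all
    # internal rates together drives the overall rate monotonically, so a sign
    # change of the constraint brackets the target.
    ones = np.ones(len(free_names))
    lo_s, hi_s = -8.0, 8.0
    g_lo, g_hi = constraint(lo_s * ones), constraint(hi_s * ones)
    if not (g_lo < 0.0 < g_hi):
        v_lo = (g_lo + 1.0) * problem.v_target
        v_hi = (g_hi + 1.0) * problem.v_target
        raise InfeasibleSpeedError(
            f"target {problem.v_target} aa/s lies outside the achievable range "
            f"[{v_lo:.6g}, {v_hi:.6g}] aa/s for shifts in [-8, 8]"
        )
    s_star = optimize.brentq(lambda s: constraint(s * ones), lo_s, hi_s, xtol=1e-12)

    # a wide default box keeps the line search away from overflow-sized
    # shifts without constraining any physically sensible solution
    bounds = [problem.bounds.get(n, (-20.0, 20.0)) for n in free_names]
    lo_b = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])
    slsqp_bounds = [
        (None if not math.isfinite(lo) else lo, None if not math.isfinite(hi) else hi)
        for lo, hi in bounds
    ]
    rng = np.random.default_rng(problem.seed)
    starts = [np.clip(s_star * ones, lo_b, hi_b)]
    for _ in range(max(problem.starts - 1, 0)):
        x0 = rng.uniform(-2.0, 2.0, size=len(free_names))
        starts.append(np.clip(x0, lo_b, hi_b))

    solutions: list[np.ndarray] = []
    for k, x0 in enumerate(starts):
        res = optimize.minimize(
            objective,
            x0,
            jac=objective_grad,
            method="SLSQP",
            bounds=slsqp_bounds,
            constraints=[{"type": "eq", "fun": constraint}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success and abs(constraint(res.x)) < 1e-6:
            solutions.append(res.x)
            logger.info(
                "multistart %d/%d converged: distance %.6g", k + 1, len(starts),
                math.sqrt(objective(res.x) + fixed_sq),
            )
        else:
            logger.info("multistart %d/%d did not converge: %s", k + 1, len(starts), res.message)
    if not solutions:
        raise RuntimeError("no multistart converged; best iterate unavailable")

    best = min(solutions, key=objective)
    spread = 0.0
    for sol in solutions:
        spread = max(spread, float(np.max(np.abs(sol - best))))

    flags = tuple(
        n for n, (lo, hi), x in zip(free_names, bounds, best)
        if (math.isfinite(lo) and abs(x - lo) < 1e-9)
        or (math.isfinite(hi) and abs(x - hi) < 1e-9)
    )
    if not flags:
        # polish the constraint; skipped for boundary minima, where moving
        # along the ray could step outside the feasible box
        best = _radial_projection(constraint, best)
    residual = abs(constraint(best))

    deltas = dict(problem.fixed_coords)
    deltas.update(zip(free_names, map(float, best)))
    shifts = BarrierShifts(deltas=deltas, reference=problem.in_vitro)
    rates = _rates_from_vector(problem, free_names, best)
    return MinimizationResult(
        delta_min=shifts,
        rates_in_vivo=rates,
        distance=distance(shifts),
        constraint_residual=residual,
        scale_factors={n: math.exp(d) for n, d in deltas.items()},
        boundary_flags=flags,
        multistart_spread=spread,
        n_converged=len(solutions),
    )


def _radial_projection(constraint, x: np.ndarray) -> np.ndarray:
    """Rescale the solution along its ray from the origin to sit exactly on the hypersurface.

    Near the optimum the constraint is monotone along the radial direction;
    the 1-D root polishes the residual from optimizer tolerance (~1e-8)
    down to working precision without leaving the optimal direction.
    """
    norm = float(np.linalg.norm(x))
    if norm == 0.0:
        return x
    direction = x / norm

    def g(s: float) -> float:
        return constraint((norm + s) * direction)

    span = max(1e-6, 1e-4 * norm)
    lo, hi = -span, span
    for _ in range(40):
        if g(lo) * g(hi) < 0:
            break
        lo *= 2.0
        hi *= 2.0
    else:
        return x
    s = optimize.brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    return (norm + s) * direction


def scale_factor_report(result: MinimizationResult) -> dict[str, float]:
    """Per-rate in-vivo/in-vitro ratios ``exp(delta)`` of a converged result."""
    report = dict(result.scale_factors)
    ref = result.delta_min.reference
    for name, factor in report.items():
        implied = result.rates_in_vivo[name] / ref[name]
        if not math.isclose(factor, implied, rel_tol=1e-12):
            raise AssertionError(f"inconsistent scale factor for {name}: {factor} vs {implied}")
    return report
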