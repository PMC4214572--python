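"""Error-polyhedron propagation of in-vitro rate uncertainties.

Each in-vitro rate carries a relative error ``eps``.  Applying all sign
combinations ``omega * (1 ± eps)`` over a chosen coordinate subset yields
``2^m`` fictitious in-vitro assays — the corners of an error polyhedron
around the mean assay in barrier space.  Re-running the constrained
minimization from every corner measures how far the predicted in-vivo
point moves; half the max–min spread of the log-predicted rates gives an
absolute coordinate error ``d_delta``, which is combined in quadrature
with ``eps`` into the relative standard deviation (RSD) of each predicted
in-vivo rate.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

from .inference import (
    InfeasibleSpeedError,
    MinimizationProblem,
    MinimizationResult,
    deduce_in_vivo_rates,
)
from .rates import INTERNAL_RATE_NAMES, RATE_NAMES, RateSet

__all__ = [
    "ErrorModel",
    "PropagationResult",
    "polyhedron_corners",
    "auto_subset",
    "propagate",
]

logger = logging.getLogger(__name__)

#: Multiplicative clamp applied when 1 - eps would make a corner rate nonpositive.
_CLAMP_FACTOR = 1e-3


@dataclass(frozen=True)
class ErrorModel:
    """Relative errors of the in-vitro rates and the corner-construction subset.

    ``rel_errors`` maps rate names (the full 13-name vocabulary) to relative
    errors ``eps >= 0``; missing names default to zero.  ``subset`` lists
    the coordinates whose errors span the polyhedron (2^m corners).
    """

    rel_errors: dict[str, float]
    subset: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.rel_errors) - set(RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rate names in rel_errors: {sorted(unknown)}")
        for name, eps in self.rel_errors.items():
            if not (math.isfinite(eps) and eps >= 0):
                raise ValueError(f"relative error of {name!r} must be >= 0, got {eps!r}")
        if not self.subset:
            raise ValueError("corner subset must be nonempty")
        unknown = set(self.subset) - set(INTERNAL_RATE_NAMES)
        if unknown:
            raise ValueError(f"corner subset must use internal rate names, got {sorted(unknown)}")
        object.__setattr__(self, "subset", tuple(self.subset))

    def eps(self, name: str) -> float:
        return self.rel_errors.get(name, 0.0)


@dataclass(frozen=True)
class PropagationResult:
    """Per-rate RSDs of the predicted in-vivo rates plus per-corner diagnostics."""

    rsd: dict[str, float]
    delta_spread: dict[str, float]
    corner_rates: dict[tuple[int, ...], RateSet]
    infeasible_corners: tuple[tuple[int, ...], ...]
    base_result: MinimizationResult


def polyhedron_corners(base: RateSet, error_model: ErrorModel) -> dict[tuple[int, ...], RateSet]:
    """Fictitious in-vitro assays at all sign combinations of the subset errors.

    Returns a mapping from the sigma-tuple (entries ±1, ordered as the
    subset) to the corner rate set ``omega * (1 + sigma*eps)``.  A corner
    factor that would be nonpositive (eps >= 1) is clamped to a small
    positive multiple of the mean rate, with a warning.
    """
    corners: dict[tuple[int, ...], RateSet] = {}
    for sigma in itertools.product((-1, 1), repeat=len(error_model.subset)):
        factors = {}
        for name, s in zip(error_model.subset, sigma):
            factor = 1.0 + s * error_model.eps(name)
            if factor <= 0.0:
                logger.warning(
                    "relative error of %s is >= 1; clamping corner factor to %g",
                    name, _CLAMP_FACTOR,
                )
                factor = _CLAMP_FACTOR
            factors[name] = factor
        corners[sigma] = base.scaled(factors, label=f"{base.label} corner {sigma}")
    return corners


def auto_subset(result: MinimizationResult, size: int = 3) -> tuple[str, ...]:
    """The ``size`` coordinates with the largest |barrier shift| at the mean solution."""
    deltas = result.delta_min.internal()
    ranked = sorted(deltas, key=lambda n: abs(deltas[n]), reverse=True)
    return tuple(ranked[:size])


def propagate(
    problem: MinimizationProblem,
    error_model: ErrorModel,
    base_result: MinimizationResult | None = None,
) -> PropagationResult:
    """Propagate in-vitro errors into RSDs of the deduced in-vivo rates.

    Re-runs the deduction from every corner assay; corners whose target
    speed is infeasible are excluded with a warning.  The RSD of each
    internal rate combines its in-vitro relative error with the corner
    spread of the log-predicted in-vivo rate in quadrature; the association
    constant is not minimized, so its RSD is its in-vitro relative error.
    """
    if base_result is None:
        base_result = deduce_in_vivo_rates(problem)
    corners = polyhedron_corners(problem.in_vitro, error_model)

    base_pred = base_result.rates_in_vivo
    per_corner_logs: dict[str, list[float]] = {n: [] for n in INTERNAL_RATE_NAMES}
    infeasible: list[tuple[int, ...]] = []
    for sigma, corner_assay in corners.items():
        corner_problem = replace(
            problem,
            in_vitro=corner_assay,
            kon_in_vivo=problem.effective_kon,
        )
        try:
            corner_result = deduce_in_vivo_rates(corner_problem)
        except (InfeasibleSpeedError, RuntimeError) as exc:
            logger.warning("corner %s excluded: %s", sigma, exc)
            infeasible.append(sigma)
            continue
        for name in INTERNAL_RATE_NAMES:
            per_corner_logs[name].append(
                math.log(corner_result.rates_in_vivo[name] / base_pred[name])
            )

    delta_spread: dict[str, float] = {}
    rsd: dict[str, float] = {}
    for name in INTERNAL_RATE_NAMES:
        logs = per_corner_logs[name]
        spread = 0.5 * (max(logs) - min(logs)) if logs else 0.0
        delta_spread[name] = spread
        rsd[name] = math.sqrt(error_model.eps(name) ** 2 + spread**2)
    rsd["kon"] = error_model.eps("kon")
    delta_spread["kon"] = 0.0
    return PropagationResult(
        rsd=rsd,
        delta_spread=delta_spread,
        corner_rates=corners,
        infeasible_corners=tuple(infeasible),
        base_result=base_result,
    )
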