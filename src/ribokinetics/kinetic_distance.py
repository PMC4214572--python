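"""Barrier-shift coordinates and the kinetic distance between two kinetics.

Each transition rate maps to a logarithmic coordinate
``delta = ln(rate / reference_rate)``, interpreted as the shift (in units of
thermal energy) of the free-energy barrier governing the transition:
``delta > 0`` means the rate is larger than in the reference assay, i.e. the
barrier is lowered.  Changes of the attempt frequency are absorbed into
``delta``.  The kinetic distance is the Euclidean norm over the barrier
shifts of all seventeen internal transitions; after tie reduction this is a
weighted norm over the twelve distinct coordinates, tied transitions
entering with their multiplicity (3 for the dissociation rate, 2 each for
recognition, conformational and processing rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .rates import INTERNAL_RATE_NAMES, TIE_MULTIPLICITY, RateSet

__all__ = [
    "BarrierShifts",
    "shift_from_rates",
    "rates_from_shifts",
    "distance",
    "translate_assay",
]


@dataclass(frozen=True)
class BarrierShifts:
    """Ordered map of barrier shifts (dimensionless, units of kT) plus the reference assay.

    The coordinate vocabulary is the twelve distinct internal rates; ``kon``
    may be carried as an additional, non-minimized coordinate.
    """

    deltas: dict[str, float]
    reference: RateSet

    def __post_init__(self) -> None:
        known = set(INTERNAL_RATE_NAMES) | {"kon"}
        unknown = set(self.deltas) - known
        if unknown:
            raise ValueError(f"unknown barrier-shift coordinates: {sorted(unknown)}")
        for name, value in self.deltas.items():
            if not math.isfinite(value):
                raise ValueError(f"barrier shift {name!r} must be finite, got {value!r}")

    def __getitem__(self, name: str) -> float:
        return self.deltas[name]

    def internal(self) -> dict[str, float]:
        """Shifts of the 12 internal coordinates, in canonical order (kon dropped)."""
        return {n: self.deltas.get(n, 0.0) for n in INTERNAL_RATE_NAMES}


def shift_from_rates(reference: RateSet, other: RateSet, include_kon: bool = True) -> BarrierShifts:
    """Barrier shifts of ``other`` relative to ``reference``.

    ``delta = ln(other / reference)`` per coordinate, so a rate that is
    larger in ``other`` (e.g. in vivo) than in the reference (in-vitro)
    assay has a positive shift, and ``rates_from_shifts`` inverts exactly.
    """
    names = (("kon",) if include_kon else ()) + INTERNAL_RATE_NAMES
    deltas = {n: math.log(other[n] / reference[n]) for n in names}
    return BarrierShifts(deltas=deltas, reference=reference)


def rates_from_shifts(shifts: BarrierShifts, label: str = "") -> RateSet:
    """Invert the coordinate transformation: ``rate = reference * exp(delta)``."""
    updates = {n: shifts.reference[n] * math.exp(d) for n, d in shifts.deltas.items()}
    return shifts.reference.with_rates(label=label or shifts.reference.label, **updates)


def distance(shifts: BarrierShifts | Mapping[str, float], include_kon: bool = False) -> float:
    """Kinetic distance: weighted Euclidean norm of the barrier shifts.

    Tied coordinates carry their transition multiplicity, so the distance
    over the reduced 12-coordinate set equals the plain Euclidean norm over
    all seventeen internal transitions.  ``kon`` is excluded by default (it
    is fixed by the diffusion argument, not minimized); pass
    ``include_kon=True`` to count it with weight one.
    """
    deltas = shifts.deltas if isinstance(shifts, BarrierShifts) else dict(shifts)
    total = 0.0
    for name in INTERNAL_RATE_NAMES:
        total += TIE_MULTIPLICITY[name] * deltas.get(name, 0.0) ** 2
    if include_kon:
        total += deltas.get("kon", 0.0) ** 2
    return math.sqrt(total)


def plot_barrier_shifts(shifts: BarrierShifts | Mapping[str, float], ax=None):
    """Bar chart of per-rate barrier shifts (positive = faster than the reference)."""
    import matplotlib.pyplot as plt

    deltas = shifts.internal() if isinstance(shifts, BarrierShifts) else dict(shifts)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    names = list(deltas)
    ax.bar(range(len(names)), [deltas[n] for n in names], color="steelblue")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel(r"barrier shift $\Delta$ ($k_BT$)")
    return ax


def translate_assay(shifts: BarrierShifts, logdiffs: Mapping[str, float],
                    new_reference: RateSet | None = None) -> BarrierShifts:
    """Re-express barrier shifts relative to a second reference assay.

    If the shifts were measured from assay A and ``logdiffs`` holds the
    coordinate-wise logarithmic differences ``ln(rate_A / rate_A')`` between
    assays A and A', the shifts from A' are obtained by coordinate-wise
    addition — a Euclidean translation of the barrier space.
    """
    unknown = set(logdiffs) - set(shifts.deltas)
    if unknown:
        raise ValueError(f"logdiffs carry coordinates absent from the shifts: {sorted(unknown)}")
    deltas = {n: d + logdiffs.get(n, 0.0) for n, d in shifts.deltas.items()}
    return BarrierShifts(deltas=deltas, reference=new_reference or shifts.reference)
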