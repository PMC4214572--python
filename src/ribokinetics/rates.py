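"""Rate-set container for the 12-state elongation cycle.

One elongation cycle is described by a continuous-time Markov process on
twelve ribosomal states (0–11).  The seventeen internal transitions of the
cycle are governed by twelve distinct first-order rates plus the bimolecular
association rate constant ``kon``; the tie structure (one dissociation rate
for the three dissociation transitions, one recognition rate for the two
recognition transitions, one conformational rate for the two Pi-release
steps, one processing rate for the two peptide-bond/translocation steps) is
encoded structurally and cannot be violated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

__all__ = [
    "RateSet",
    "INTERNAL_RATE_NAMES",
    "RATE_NAMES",
    "TIE_MULTIPLICITY",
]

#: The 12 distinct internal (first-order) transition rates, in the order in
#: which the transitions appear along the cognate, near-cognate and
#: non-cognate branches of the cycle.
INTERNAL_RATE_NAMES: tuple[str, ...] = (
    "omega_off",
    "omega_rec",
    "omega_back_c",
    "omega_gtp_c",
    "omega_conf",
    "omega_acc_c",
    "omega_drop_c",
    "omega_rej_n",
    "omega_gtp_n",
    "omega_acc_n",
    "omega_drop_n",
    "omega_proc",
)

#: Full rate vocabulary: association rate constant plus the internal rates.
RATE_NAMES: tuple[str, ...] = ("kon",) + INTERNAL_RATE_NAMES

#: Number of internal transitions sharing each distinct rate.  The three
#: dissociations (states 1, 6, 11 -> 0) share omega_off, the two recognition
#: steps (1 -> 2, 6 -> 7) share omega_rec, the two conformational/Pi-release
#: steps (3 -> 4, 8 -> 9) share omega_conf and the two processing steps
#: (5 -> 0', 10 -> 0') share omega_proc; 3+2+2+2 + 8*1 = 17 transitions.
TIE_MULTIPLICITY: dict[str, int] = {
    name: 1 for name in INTERNAL_RATE_NAMES
}
TIE_MULTIPLICITY["omega_off"] = 3
TIE_MULTIPLICITY["omega_rec"] = 2
TIE_MULTIPLICITY["omega_conf"] = 2
TIE_MULTIPLICITY["omega_proc"] = 2

assert sum(TIE_MULTIPLICITY.values()) == 17


@dataclass(frozen=True)
class RateSet:
    """Association rate constant and the 12 distinct internal rates.

    Parameters
    ----------
    kon
        Bimolecular association rate constant for initial binding of a
        ternary complex, 1/(µM·s).
    omega_off
        Initial dissociation rate from states 1, 6 and 11 back to 0, 1/s.
    omega_rec
        Codon recognition rate (1 -> 2 and 6 -> 7), 1/s.
    omega_back_c
        Cognate backward rate from the recognition state (2 -> 1), 1/s.
    omega_gtp_c
        Cognate GTPase activation + GTP hydrolysis rate (2 -> 3), 1/s.
    omega_conf
        Pi-release/conformational rate (3 -> 4 and 8 -> 9), 1/s.
    omega_acc_c
        Cognate accommodation rate (4 -> 5), 1/s.
    omega_drop_c
        Cognate rejection after proofreading (4 -> 0), 1/s.
    omega_rej_n
        Near-cognate initial-selection rejection rate (7 -> 6), 1/s.
    omega_gtp_n
        Near-cognate GTPase activation + hydrolysis rate (7 -> 8), 1/s.
    omega_acc_n
        Near-cognate accommodation rate (9 -> 10), 1/s.
    omega_drop_n
        Near-cognate rejection after proofreading (9 -> 0), 1/s.
    omega_proc
        Processing rate: peptide-bond formation plus translocation
        (5 -> 0' and 10 -> 0'), 1/s.
    temperature
        Temperature tag in Kelvin.
    label
        Free-text provenance label.
    """

    kon: float
    omega_off: float
    omega_rec: float
    omega_back_c: float
    omega_gtp_c: float
    omega_conf: float
    omega_acc_c: float
    omega_drop_c: float
    omega_rej_n: float
    omega_gtp_n: float
    omega_acc_n: float
    omega_drop_n: float
    omega_proc: float
    temperature: float = 310.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"rate {name!r} must be finite, got {value!r}")
            if value <= 0.0:
                raise ValueError(f"rate {name!r} must be strictly positive, got {value}")
        if not (isinstance(self.temperature, (int, float)) and self.temperature > 0):
            raise ValueError(f"temperature must be positive Kelvin, got {self.temperature!r}")

    def __getitem__(self, name: str) -> float:
        if name not in RATE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def internal(self) -> dict[str, float]:
        """The 12 internal rates as an ordered mapping (kon excluded)."""
        return {name: getattr(self, name) for name in INTERNAL_RATE_NAMES}

    def as_dict(self) -> dict[str, float]:
        """All 13 rates (kon first) as an ordered mapping."""
        return {name: getattr(self, name) for name in RATE_NAMES}

    def with_rates(self, label: str | None = None, **updates: float) -> "RateSet":
        """Copy with some rates replaced (validation re-runs)."""
        unknown = set(updates) - set(RATE_NAMES)
        if unknown:
            raise KeyError(f"unknown rate names: {sorted(unknown)}")
        if label is not None:
            updates["label"] = label  # type: ignore[assignment]
        return replace(self, **updates)

    def scaled(self, factors: Mapping[str, float], label: str | None = None) -> "RateSet":
        """Copy with the given rates multiplied by per-rate factors."""
        updates = {name: getattr(self, name) * f for name, f in factors.items()}
        return self.with_rates(label=label, **updates)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())
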