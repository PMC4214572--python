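"""Arrhenius-style extrapolation of in-vitro rates between temperatures.

Transition-state theory writes each rate as
``omega(T) = (kB*T/h) * exp(dS/kB) * exp(-dH/(kB*T))`` with temperature-
independent activation enthalpy ``dH`` and entropy ``dS``.  Taking the
ratio of a rate to a reference rate measured at both temperatures
eliminates the attempt frequency; eliminating the enthalpy between the two
temperatures and dropping the (small) entropy-difference term yields the
reference-anchored extrapolation

    omega_i(T2) = omega_ref(T2) * (omega_i(T1) / omega_ref(T1)) ** (T1/T2)

which is exact whenever the rate and the reference share the same
activation entropy.  The bimolecular association constant is extrapolated
with a plain Arrhenius factor and a known activation energy instead.
"""

from __future__ import annotations

import math

__all__ = [
    "R_KCAL_PER_MOL_K",
    "DEFAULT_T_COLD",
    "DEFAULT_T_WARM",
    "DEFAULT_EA_BINDING_KCAL",
    "extrapolate_rate",
    "extrapolate_kon",
    "tst_rate",
]

#: Gas constant in kcal/(mol·K).
R_KCAL_PER_MOL_K = 1.987204259e-3

#: The two assay temperatures (20 °C and 37 °C, rounded as in common usage).
DEFAULT_T_COLD = 293.0
DEFAULT_T_WARM = 310.0

#: Activation energy for initial ternary-complex binding, kcal/mol.
DEFAULT_EA_BINDING_KCAL = 2.4


def _check_positive(**values: float) -> None:
    for name, value in values.items():
        if not (math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def extrapolate_rate(
    rate_at_t1: float,
    reference_rate_at_t1: float,
    reference_rate_at_t2: float,
    t1: float = DEFAULT_T_COLD,
    t2: float = DEFAULT_T_WARM,
) -> float:
    """Extrapolate a first-order rate from ``t1`` to ``t2`` via a reference rate.

    Exact when the rate and the reference rate have equal activation
    entropies; otherwise the neglected correction is suppressed by the
    relative temperature difference.
    """
    _check_positive(
        rate_at_t1=rate_at_t1,
        reference_rate_at_t1=reference_rate_at_t1,
        reference_rate_at_t2=reference_rate_at_t2,
        t1=t1, t2=t2,
    )
    return reference_rate_at_t2 * (rate_at_t1 / reference_rate_at_t1) ** (t1 / t2)


def extrapolate_kon(
    kon_at_t1: float,
    t1: float = DEFAULT_T_COLD,
    t2: float = DEFAULT_T_WARM,
    e_a: float = DEFAULT_EA_BINDING_KCAL,
) -> float:
    """Arrhenius extrapolation of the association rate constant.

    ``kon(T2) = kon(T1) * exp(-E_a/R * (1/T2 - 1/T1))`` with ``E_a`` in
    kcal/mol.
    """
    _check_positive(kon_at_t1=kon_at_t1, t1=t1, t2=t2)
    if not math.isfinite(e_a):
        raise ValueError(f"activation energy must be finite, got {e_a!r}")
    return kon_at_t1 * math.exp(-(e_a / R_KCAL_PER_MOL_K) * (1.0 / t2 - 1.0 / t1))


def tst_rate(dh_kcal: float, ds_kcal_per_k: float, t: float) -> float:
    """Transition-state-theory rate for given activation enthalpy/entropy.

    ``omega = (kB*T/h) * exp(dS/R) * exp(-dH/(R*T))`` with ``dH`` in
    kcal/mol and ``dS`` in kcal/(mol·K).  Used as the forward-generating
    oracle for the extrapolation tests.
    """
    _check_positive(t=t)
    kb_over_h = 2.083661912e10  # 1/(K·s)
    return kb_over_h * t * math.exp(ds_kcal_per_k / R_KCAL_PER_MOL_K) * math.exp(
        -dh_kcal / (R_KCAL_PER_MOL_K * t)
    )
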