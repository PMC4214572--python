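"""Missense error frequencies and the selection/proofreading coefficients.

A missense error occurs when a near-cognate ternary complex is fully
accommodated, incorporating a wrong amino acid.  Because every elongation
cycle ends with exactly one accommodation (cognate or near-cognate), the
error probability for a particular near-cognate species ``j`` with
concentration ``c_j`` is its share of the total accommodation flux,

    p_error(j) = c_j * v_nea / (c_cog * v_cog + c_nea * v_nea),

with the concentration-independent accommodation probabilities ``v_cog``
and ``v_nea`` of the two branches.  Non-cognate binding only delays the
cycle and drops out of the ratio, so the error frequency is provably
independent of the non-cognate concentration.
"""

from __future__ import annotations

import math
from typing import Mapping

from .decoding import ConcentrationProfile, DecodingMatrix, build_codon_contexts
from .elongation import CodonContext, _branch_quantities
from .rates import RateSet

__all__ = [
    "missense_probability",
    "average_missense",
    "selection_coefficients",
    "coefficient_ratios",
    "error_reduction_factor",
]


def missense_probability(rates: RateSet, ctx: CodonContext, c_species: float) -> float:
    """Probability that the queried near-cognate species is fully accommodated.

    ``c_species`` (µM) is the concentration of the single near-cognate
    species under consideration; it must not exceed the pooled near-cognate
    concentration of the context.
    """
    if not (0.0 <= c_species <= ctx.c_nea * (1.0 + 1e-12)):
        raise ValueError(
            f"species concentration {c_species} µM exceeds the pooled near-cognate "
            f"concentration {ctx.c_nea} µM of codon {ctx.codon!r}"
        )
    if ctx.c_cog <= 0.0:
        raise ValueError(f"codon {ctx.codon!r} has zero cognate concentration")
    v_cog, v_nea, _, _ = _branch_quantities(rates)
    return c_species * v_nea / (ctx.c_cog * v_cog + ctx.c_nea * v_nea)


def average_missense(
    rates: RateSet,
    matrix: DecodingMatrix,
    conc: ConcentrationProfile,
    usage: Mapping[str, float],
    trna_id: str,
) -> float:
    """Codon-usage-weighted missense error frequency of one tRNA species.

    Averages the per-codon misreading probability over all codons that are
    near-cognate to the species, with weights normalized over that codon
    set.
    """
    if trna_id not in matrix.trnas:
        raise KeyError(f"unknown tRNA species {trna_id!r}")
    near_codons = matrix.near_cognate_codons(trna_id)
    if not near_codons:
        raise ValueError(f"tRNA {trna_id!r} has no near-cognate codons")
    contexts = build_codon_contexts(matrix, conc, usage)
    c_species = conc[trna_id]
    weight_sum = 0.0
    acc = 0.0
    for codon in near_codons:
        b = float(usage[codon])
        if b == 0.0:
            continue
        acc += b * missense_probability(rates, contexts[codon], c_species)
        weight_sum += b
    if weight_sum == 0.0:
        raise ValueError(f"all near-cognate codons of {trna_id!r} have zero usage")
    return acc / weight_sum


def selection_coefficients(rates: RateSet) -> tuple[float, float]:
    """Efficiencies of initial selection and proofreading.

    The initial-selection coefficient is the ratio of the probabilities
    that a cognate versus a near-cognate ternary complex, once initially
    bound, proceeds through GTPase activation and GTP hydrolysis (the
    reversible recognition loop resolved).  The proofreading coefficient is
    the ratio of the post-hydrolysis accommodation probabilities.  Both are
    concentration independent and equal one when the cognate and
    near-cognate branches carry identical rates.
    """
    r = rates
    p_hyd_c = _pass_initial_selection(r.omega_rec, r.omega_off, r.omega_gtp_c, r.omega_back_c)
    p_hyd_n = _pass_initial_selection(r.omega_rec, r.omega_off, r.omega_gtp_n, r.omega_rej_n)
    initial_selection = p_hyd_c / p_hyd_n
    p_acc_c = r.omega_acc_c / (r.omega_acc_c + r.omega_drop_c)
    p_acc_n = r.omega_acc_n / (r.omega_acc_n + r.omega_drop_n)
    proofreading = p_acc_c / p_acc_n
    return initial_selection, proofreading


def _pass_initial_selection(rec: float, off: float, gtp: float, back: float) -> float:
    p1 = rec / (rec + off)
    p2 = gtp / (gtp + back)
    return p1 * p2 / (off / (rec + off) + p1 * p2)


def coefficient_ratios(rates_a: RateSet, rates_b: RateSet) -> tuple[float, float]:
    """Ratios (a/b) of the initial-selection and proofreading coefficients of two rate sets."""
    ia, pa = selection_coefficients(rates_a)
    ib, pb = selection_coefficients(rates_b)
    return ia / ib, pa / pb


def error_reduction_factor(rates_reference: RateSet, rates_improved: RateSet,
                           ctx: CodonContext, c_species: float | None = None) -> float:
    """Fold reduction of the missense error between two rate sets at identical concentrations."""
    c = ctx.c_nea if c_species is None else c_species
    return missense_probability(rates_reference, ctx, c) / missense_probability(rates_improved, ctx, c)
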