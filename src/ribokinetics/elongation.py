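"""Codon-specific 12-state Markov model of one translation-elongation cycle.

The cycle starts in state 0 (empty A site).  Initial binding of a cognate,
near-cognate or non-cognate ternary complex (pseudo-first-order rates
``kon*c_cog``, ``kon*c_nea``, ``kon*c_non``) leads into the cognate branch
(states 1–5), the near-cognate branch (states 6–10), or the dead-end
non-cognate state 11.  Full accommodation (entry into state 5 or 10) ends
tRNA selection; the processing step (rate ``omega_proc``) completes the
cycle.

This module provides the analytic dwell-time decomposition of the
codon-specific accommodation time, the codon-specific and overall elongation
rates, and two independent oracles: an absorbing-Markov-chain linear solve
and an exact stochastic (Gillespie) simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .rates import RateSet

__all__ = [
    "CodonContext",
    "DwellDecomposition",
    "NonCompletingCycleError",
    "association_rates",
    "branch_probabilities",
    "dwell_decomposition",
    "accommodation_time",
    "codon_elongation_rate",
    "codon_elongation_time",
    "overall_elongation_rate",
    "mfpt_oracle",
    "gillespie_cycle",
    "GillespieSample",
]


class NonCompletingCycleError(ValueError):
    """Raised when the elongation cycle can never reach full accommodation."""


@dataclass(frozen=True)
class CodonContext:
    """Per-codon concentrations of free ternary complexes and codon usage.

    ``c_cog``, ``c_nea`` and ``c_non`` are the summed concentrations (µM) of
    the cognate, near-cognate and non-cognate ternary-complex species for
    this codon; ``usage`` is the probability that a translating ribosome
    encounters the codon.
    """

    codon: str
    c_cog: float
    c_nea: float
    c_non: float
    usage: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("c_cog", "c_nea", "c_non"):
            value = getattr(self, attr)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{attr} must be a finite non-negative concentration, got {value!r}")
        if not (0.0 <= self.usage <= 1.0):
            raise ValueError(f"usage must lie in [0, 1], got {self.usage!r}")


@dataclass(frozen=True)
class DwellDecomposition:
    """The four dwell-time components of the accommodation time.

    ``t0`` is the total time spent in state 0 during one complete cycle,
    ``t_non`` the total time bound to a non-cognate complex (state 11),
    ``t_cog`` the total time in the intermediate cognate states 1–4 and
    ``t_near`` the total time in the intermediate near-cognate states 6–9.
    ``v_ratio_cog``/``v_ratio_nea`` are the dimensionless, concentration-
    independent probabilities that a cognate/near-cognate complex, once
    bound, becomes fully accommodated; ``tau_cog``/``tau_nea`` are the
    concentration-independent mean residence times (s) in the respective
    intermediate states per initial-binding event.
    """

    t0: float
    t_non: float
    t_cog: float
    t_near: float
    v_ratio_cog: float
    v_ratio_nea: float
    tau_cog: float
    tau_nea: float

    @property
    def total(self) -> float:
        """Accommodation time: sum of the four dwell components."""
        return self.t0 + self.t_non + self.t_cog + self.t_near

    def as_dict(self) -> dict[str, float]:
        return {
            "t0": self.t0,
            "t_non": self.t_non,
            "t_cog": self.t_cog,
            "t_near": self.t_near,
            "v_ratio_cog": self.v_ratio_cog,
            "v_ratio_nea": self.v_ratio_nea,
            "tau_cog": self.tau_cog,
            "tau_nea": self.tau_nea,
        }


def association_rates(rates: RateSet, ctx: CodonContext) -> tuple[float, float, float]:
    """Pseudo-first-order binding rates (1/s) for cognate, near- and non-cognate complexes."""
    return (rates.kon * ctx.c_cog, rates.kon * ctx.c_nea, rates.kon * ctx.c_non)


def branch_probabilities(rates: RateSet) -> dict[int, dict[str, float]]:
    """Splitting (exit) probabilities at each multi-exit state.

    For every state with more than one exit (1, 2, 4, 6, 7, 9) the exit
    probability of each transition is its rate divided by the total exit
    rate of the state; each set sums to one.
    """
    r = rates
    return {
        1: _split(omega_rec=r.omega_rec, omega_off=r.omega_off),
        2: _split(omega_gtp_c=r.omega_gtp_c, omega_back_c=r.omega_back_c),
        4: _split(omega_acc_c=r.omega_acc_c, omega_drop_c=r.omega_drop_c),
        6: _split(omega_rec=r.omega_rec, omega_off=r.omega_off),
        7: _split(omega_gtp_n=r.omega_gtp_n, omega_rej_n=r.omega_rej_n),
        9: _split(omega_acc_n=r.omega_acc_n, omega_drop_n=r.omega_drop_n),
    }


def _split(**exits: float) -> dict[str, float]:
    total = sum(exits.values())
    return {name: value / total for name, value in exits.items()}


def _branch_quantities(rates: RateSet) -> tuple[float, float, float, float]:
    """Concentration-independent branch quantities.

    Returns ``(v_cog, v_nea, tau_cog, tau_nea)`` where ``v`` is the
    probability that an initially bound cognate/near-cognate complex becomes
    fully accommodated (rather than the ribosome returning to state 0) and
    ``tau`` is the mean total residence time in the branch's intermediate
    states per initial-binding event.

    Both follow from first-step analysis of the branch.  The recognition
    state and the pre-hydrolysis state form a reversible loop (1<->2 for the
    cognate branch, 6<->7 for the near-cognate branch); GTP hydrolysis and
    the conformational step are irreversible; the proofreading state splits
    between accommodation and rejection.
    """
    r = rates
    v_cog, tau_cog = _one_branch(
        fwd1=r.omega_rec, back1=r.omega_off,
        fwd2=r.omega_gtp_c, back2=r.omega_back_c,
        conf=r.omega_conf,
        acc=r.omega_acc_c, drop=r.omega_drop_c,
    )
    v_nea, tau_nea = _one_branch(
        fwd1=r.omega_rec, back1=r.omega_off,
        fwd2=r.omega_gtp_n, back2=r.omega_rej_n,
        conf=r.omega_conf,
        acc=r.omega_acc_n, drop=r.omega_drop_n,
    )
    return v_cog, v_nea, tau_cog, tau_nea


def _one_branch(
    *, fwd1: float, back1: float, fwd2: float, back2: float,
    conf: float, acc: float, drop: float,
) -> tuple[float, float]:
    # splitting probabilities at the two loop states and the proofreading state
    p1 = fwd1 / (fwd1 + back1)          # initial-binding state -> recognition state
    p2 = fwd2 / (fwd2 + back2)          # recognition state -> GTP hydrolysis
    p_acc = acc / (acc + drop)          # proofreading state -> accommodation
    # expected visit counts per entry into the branch, resolving the loop;
    # 1 - p1*(1-p2) written as a sum of positives to avoid cancellation
    denom = back1 / (fwd1 + back1) + p1 * p2
    n1 = 1.0 / denom                    # initial-binding state (1 or 6)
    n2 = p1 / denom                     # recognition state (2 or 7)
    n3 = n2 * p2                        # post-hydrolysis state (3 or 8)
    n4 = n3                             # proofreading state (4 or 9)
    v = n4 * p_acc                      # probability of full accommodation
    tau = (
        n1 / (fwd1 + back1)
        + n2 / (fwd2 + back2)
        + n3 / conf
        + n4 / (acc + drop)
    )
    return v, tau


def dwell_decomposition(rates: RateSet, ctx: CodonContext) -> DwellDecomposition:
    """Closed-form decomposition of the codon-specific accommodation time.

    The mean time from state 0 to full accommodation decomposes into the
    total dwell in state 0, in the non-cognate state 11, and in the
    intermediate states of the cognate and near-cognate branches:

    * ``t0 = 1 / (kon * (c_cog*v_cog + c_nea*v_nea))`` — the mean number of
      visits to state 0 is the inverse of the per-binding accommodation
      probability, and each visit lasts ``1/(kon*(c_cog+c_nea+c_non))``.
    * ``t_non = t0 * kon * c_non / omega_off`` — proportional to the
      non-cognate concentration.
    * ``t_cog = t0 * kon * c_cog * tau_cog`` and
      ``t_near = t0 * kon * c_nea * tau_nea`` with the concentration-
      independent branch time scales ``tau``.
    """
    if ctx.c_cog <= 0.0:
        raise NonCompletingCycleError(
            f"codon {ctx.codon!r}: cognate concentration is zero, the cycle never completes"
        )
    v_cog, v_nea, tau_cog, tau_nea = _branch_quantities(rates)
    t0 = 1.0 / (rates.kon * (ctx.c_cog * v_cog + ctx.c_nea * v_nea))
    t_non = t0 * rates.kon * ctx.c_non / rates.omega_off
    t_cog = t0 * rates.kon * ctx.c_cog * tau_cog
    t_near = t0 * rates.kon * ctx.c_nea * tau_nea
    return DwellDecomposition(
        t0=t0, t_non=t_non, t_cog=t_cog, t_near=t_near,
        v_ratio_cog=v_cog, v_ratio_nea=v_nea,
        tau_cog=tau_cog, tau_nea=tau_nea,
    )


def accommodation_time(rates: RateSet, ctx: CodonContext) -> float:
    """Mean first-passage time (s) from state 0 to full accommodation (state 5 or 10)."""
    return dwell_decomposition(rates, ctx).total


def codon_elongation_time(rates: RateSet, ctx: CodonContext) -> float:
    """Codon-specific elongation time (s): accommodation time plus processing time."""
    return accommodation_time(rates, ctx) + 1.0 / rates.omega_proc


def codon_elongation_rate(rates: RateSet, ctx: CodonContext) -> float:
    """Codon-specific elongation rate (aa/s)."""
    return 1.0 / codon_elongation_time(rates, ctx)


def overall_elongation_rate(rates: RateSet, contexts) -> float:
    """Overall elongation rate (aa/s): inverse usage-weighted mean elongation time.

    ``contexts`` is an iterable of :class:`CodonContext` whose usages must be
    normalized to one.  Codons with zero usage are skipped; a codon with
    positive usage but zero cognate concentration makes the average diverge
    and raises :class:`NonCompletingCycleError`.
    """
    contexts = list(contexts)
    total_usage = sum(c.usage for c in contexts)
    if not math.isclose(total_usage, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"codon usages must sum to 1, got {total_usage}")
    mean_time = 0.0
    for ctx in contexts:
        if ctx.usage == 0.0:
            continue
        mean_time += ctx.usage * codon_elongation_time(rates, ctx)
    return 1.0 / mean_time


def mean_accommodation_time(rates: RateSet, contexts) -> float:
    """Usage-weighted mean accommodation time (s) over a context set."""
    return sum(
        ctx.usage * accommodation_time(rates, ctx)
        for ctx in contexts
        if ctx.usage > 0.0
    )


# ---------------------------------------------------------------------------
# oracles

#: Transient states of the absorbing chain, in matrix order.
_TRANSIENT_STATES: tuple[int, ...] = (0, 1, 2, 3, 4, 6, 7, 8, 9, 11)


def _transient_generator(rates: RateSet, ctx: CodonContext) -> list[list[Fraction]]:
    """Generator matrix restricted to the transient states (absorption at 5/10).

    Built in exact rational arithmetic so that the diagonal balances the
    exit rates without rounding; the first-passage system can be extremely
    ill-conditioned and float rounding of the balance would bias it.
    """
    idx = {s: i for i, s in enumerate(_TRANSIENT_STATES)}
    n = len(_TRANSIENT_STATES)
    q = [[Fraction(0) for _ in range(n)] for _ in range(n)]
    r = rates

    def add(a: int, b: int | None, rate: float) -> None:
        q[idx[a]][idx[a]] -= Fraction(rate)
        if b is not None:
            q[idx[a]][idx[b]] += Fraction(rate)

    add(0, 1, r.kon * ctx.c_cog)
    add(0, 6, r.kon * ctx.c_nea)
    add(0, 11, r.kon * ctx.c_non)
    add(1, 0, r.omega_off)
    add(1, 2, r.omega_rec)
    add(2, 1, r.omega_back_c)
    add(2, 3, r.omega_gtp_c)
    add(3, 4, r.omega_conf)
    add(4, None, r.omega_acc_c)     # absorption into state 5
    add(4, 0, r.omega_drop_c)
    add(6, 0, r.omega_off)
    add(6, 7, r.omega_rec)
    add(7, 6, r.omega_rej_n)
    add(7, 8, r.omega_gtp_n)
    add(8, 9, r.omega_conf)
    add(9, None, r.omega_acc_n)     # absorption into state 10
    add(9, 0, r.omega_drop_n)
    add(11, 0, r.omega_off)
    return q


def mfpt_oracle(rates: RateSet, ctx: CodonContext) -> tuple[float, dict[int, float]]:
    """Absorbing-chain linear solve: mean accommodation time and per-state occupancies.

    Builds the explicit generator of the 12-state process with absorption at
    full accommodation (states 5 and 10) and solves the first-passage
    system.  Returns the mean absorption time starting from state 0 and the
    expected total time spent in each transient state.  This routine is
    deliberately independent of :func:`dwell_decomposition` and serves as
    its oracle.
    """
    q = _transient_generator(rates, ctx)
    n = len(_TRANSIENT_STATES)
    # occupancy system (-Q)^T x = e0, solved exactly: the first-passage
    # system can be arbitrarily ill-conditioned in float arithmetic
    a = [[-q[j][i] for j in range(n)] for i in range(n)]
    b = [Fraction(1) if i == 0 else Fraction(0) for i in range(n)]
    occupancy = _solve_rational(a, b)
    if occupancy is None or any(x < 0 for x in occupancy):
        raise NonCompletingCycleError("absorbing state unreachable from state 0")
    per_state = {s: float(occupancy[i]) for i, s in enumerate(_TRANSIENT_STATES)}
    return float(sum(occupancy)), per_state


def _solve_rational(a: list[list[Fraction]], b: list[Fraction]) -> list[Fraction] | None:
    """Exact Gaussian elimination with partial pivoting; None when singular."""
    n = len(b)
    for col in range(n):
        pivot = max(range(col, n), key=lambda row: abs(a[row][col]))
        if a[pivot][col] == 0:
            return None
        a[col], a[pivot] = a[pivot], a[col]
        b[col], b[pivot] = b[pivot], b[col]
        inv = 1 / a[col][col]
        for row in range(col + 1, n):
            factor = a[row][col] * inv
            if factor == 0:
                continue
            for k in range(col, n):
                a[row][k] -= factor * a[col][k]
            b[row] -= factor * b[col]
    x = [Fraction(0)] * n
    for row in range(n - 1, -1, -1):
        acc = b[row] - sum(a[row][k] * x[k] for k in range(row + 1, n))
        x[row] = acc / a[row][row]
    return x


@dataclass(frozen=True)
class GillespieSample:
    """Samples from exact stochastic simulation of complete elongation cycles.

    ``cycle_times`` include the final processing dwell; ``near_accommodated``
    marks cycles that ended with accommodation of a near-cognate complex;
    ``residence[:, s]`` is the total time each cycle spent in state ``s``
    (states 0–11; 5 and 10 hold the processing dwell).
    """

    cycle_times: np.ndarray
    near_accommodated: np.ndarray
    residence: np.ndarray

    @property
    def n(self) -> int:
        return self.cycle_times.shape[0]


def gillespie_cycle(rates: RateSet, ctx: CodonContext, n: int, seed: int) -> GillespieSample:
    """Simulate ``n`` complete elongation cycles with an explicit seed."""
    if n < 1:
        raise ValueError(f"replicate count must be >= 1, got {n}")
    if ctx.c_cog <= 0.0:
        raise NonCompletingCycleError(
            f"codon {ctx.codon!r}: cognate concentration is zero, the cycle never completes"
        )
    rng = np.random.default_rng(seed)
    r = rates
    a_c, a_n, a_x = association_rates(rates, ctx)
    a_tot = a_c + a_n + a_x

    # (total exit rate, [(probability, next state), ...]) per transient state;
    # next state None encodes full accommodation (5 for cognate, 10 for near).
    table: dict[int, tuple[float, list[tuple[float, int | None]]]] = {
        0: (a_tot, [(a_c / a_tot, 1), (a_n / a_tot, 6), (a_x / a_tot, 11)]),
        1: (r.omega_off + r.omega_rec, [(r.omega_rec / (r.omega_off + r.omega_rec), 2), (1.0, 0)]),
        2: (r.omega_back_c + r.omega_gtp_c, [(r.omega_gtp_c / (r.omega_back_c + r.omega_gtp_c), 3), (1.0, 1)]),
        3: (r.omega_conf, [(1.0, 4)]),
        4: (r.omega_acc_c + r.omega_drop_c, [(r.omega_acc_c / (r.omega_acc_c + r.omega_drop_c), None), (1.0, 0)]),
        6: (r.omega_off + r.omega_rec, [(r.omega_rec / (r.omega_off + r.omega_rec), 7), (1.0, 0)]),
        7: (r.omega_rej_n + r.omega_gtp_n, [(r.omega_gtp_n / (r.omega_rej_n + r.omega_gtp_n), 8), (1.0, 6)]),
        8: (r.omega_conf, [(1.0, 9)]),
        9: (r.omega_acc_n + r.omega_drop_n, [(r.omega_acc_n / (r.omega_acc_n + r.omega_drop_n), None), (1.0, 0)]),
        11: (r.omega_off, [(1.0, 0)]),
    }

    cycle_times = np.empty(n)
    near = np.zeros(n, dtype=bool)
    residence = np.zeros((n, 12))
    exp = rng.exponential
    uniform = rng.random
    for i in range(n):
        state: int | None = 0
        row = residence[i]
        while True:
            total, exits = table[state]
            row[state] += exp(1.0 / total)
            u = uniform()
            acc = 0.0
            nxt = exits[-1][1]
            for prob, candidate in exits[:-1]:
                acc += prob
                if u < acc:
                    nxt = candidate
                    break
            prev, state = state, nxt
            if state is None:
                near[i] = prev == 9
                acc_state = 10 if near[i] else 5
                row[acc_state] += exp(1.0 / r.omega_proc)
                break
        cycle_times[i] = row.sum()
    return GillespieSample(cycle_times=cycle_times, near_accommodated=near, residence=residence)
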