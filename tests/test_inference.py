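"""Processing-rate calibration and constrained kinetic-distance minimization."""

import math

import numpy as np
import pytest

from ribokinetics import (
    CodonContext,
    InfeasibleSpeedError,
    MinimizationProblem,
    TIE_MULTIPLICITY,
    accommodation_time,
    calibrate_processing_rate,
    deduce_in_vivo_rates,
    overall_elongation_rate,
    scale_factor_report,
)
from ribokinetics.fixtures import random_rate_set
from ribokinetics.inference import _rates_from_vector
from ribokinetics.rates import INTERNAL_RATE_NAMES
from conftest import random_instance


class TestCalibration:
    @pytest.mark.parametrize("seed", range(50))
    def test_round_trip_recovers_processing_rate(self, seed):
        rng = np.random.default_rng(1000 + seed)
        rates = random_rate_set(rng)
        ctx = CodonContext("AAA", *np.exp(rng.uniform(np.log(0.1), np.log(10), 3)), usage=1.0)
        v = overall_elongation_rate(rates, [ctx])
        recovered = calibrate_processing_rate(rates, [ctx], v)
        assert recovered == pytest.approx(rates.omega_proc, rel=1e-9)

    def test_closed_form_single_codon(self, moderate_rates, simple_context):
        v = 0.8 / (accommodation_time(moderate_rates, simple_context) + 1.0)
        w = calibrate_processing_rate(moderate_rates, [simple_context], v)
        closed = 1.0 / (1.0 / v - accommodation_time(moderate_rates, simple_context))
        assert w == pytest.approx(closed, rel=1e-9)

    def test_slow_speed_limit_gives_small_rate(self, moderate_rates, simple_context):
        w = calibrate_processing_rate(moderate_rates, [simple_context], 1e-6)
        assert 0 < w < 2e-6

    def test_infeasible_speed_raises(self, moderate_rates, simple_context):
        v_sup = 1.0 / accommodation_time(moderate_rates, simple_context)
        with pytest.raises(InfeasibleSpeedError):
            calibrate_processing_rate(moderate_rates, [simple_context], v_sup * 1.01)
        with pytest.raises(ValueError):
            calibrate_processing_rate(moderate_rates, [simple_context], -1.0)


class TestDeduction:
    def test_self_target_sits_at_the_origin(self, small_fixture, small_contexts):
        rates = small_fixture.rates
        v = overall_elongation_rate(rates, small_contexts)
        problem = MinimizationProblem(
            in_vitro=rates, contexts=small_contexts, v_target=v,
            kon_in_vivo=rates.kon, starts=4, seed=0,
        )
        result = deduce_in_vivo_rates(problem)
        assert result.distance < 1e-6
        assert result.constraint_residual < 1e-8

    @pytest.mark.parametrize("size", [0.25, 0.5, 1.0, 2.0])
    def test_injected_perturbation_is_matched_or_beaten(self, size, small_fixture, small_contexts):
        rates = small_fixture.rates
        perturbed = rates.scaled({"omega_gtp_c": math.exp(size)})
        v_target = overall_elongation_rate(perturbed.with_rates(kon=rates.kon), small_contexts)
        problem = MinimizationProblem(
            in_vitro=rates, contexts=small_contexts, v_target=v_target,
            kon_in_vivo=rates.kon, starts=6, seed=1,
        )
        result = deduce_in_vivo_rates(problem)
        assert result.constraint_residual <= 1e-8
        assert result.distance <= size + 1e-6
        assert result.multistart_spread <= 1e-3

    def test_kkt_gradient_parallelism_at_interior_solution(self, small_fixture, small_contexts):
        # at an interior optimum the weighted shift vector is parallel to the
        # constraint gradient (the distance sphere touches the hypersurface)
        rates = small_fixture.rates
        v_target = 1.25 * overall_elongation_rate(rates, small_contexts)
        problem = MinimizationProblem(
            in_vitro=rates, contexts=small_contexts, v_target=v_target,
            kon_in_vivo=rates.kon, starts=4, seed=2,
        )
        result = deduce_in_vivo_rates(problem)
        assert not result.boundary_flags
        names = list(INTERNAL_RATE_NAMES)
        x = np.array([result.delta_min[n] for n in names])
        weights = np.array([TIE_MULTIPLICITY[n] for n in names], float)

        def v_of(vec):
            return overall_elongation_rate(
                _rates_from_vector(problem, names, vec), small_contexts
            )

        h = 1e-6
        grad = np.array([
            (v_of(x + h * np.eye(len(names))[i]) - v_of(x - h * np.eye(len(names))[i])) / (2 * h)
            for i in range(len(names))
        ])
        weighted = weights * x
        cos = np.dot(grad, weighted) / (np.linalg.norm(grad) * np.linalg.norm(weighted))
        assert abs(abs(cos) - 1.0) < 1e-4

    def test_fixed_coordinates_are_honored_and_counted(self, small_fixture, small_contexts):
        rates = small_fixture.rates
        v = overall_elongation_rate(rates, small_contexts)
        problem = MinimizationProblem(
            in_vitro=rates, contexts=small_contexts, v_target=v,
            kon_in_vivo=rates.kon, fixed_coords={"omega_conf": 0.4}, starts=4, seed=3,
        )
        result = deduce_in_vivo_rates(problem)
        assert result.delta_min["omega_conf"] == 0.4
        assert result.rates_in_vivo.omega_conf == pytest.approx(
            rates.omega_conf * math.exp(0.4), rel=1e-12
        )
        # the pinned coordinate still contributes its tied weight to the distance
        assert result.distance >= math.sqrt(TIE_MULTIPLICITY["omega_conf"]) * 0.4 - 1e-9

    def test_bounds_produce_boundary_flags(self, small_fixture, small_contexts):
        rates = small_fixture.rates
        v_target = 1.5 * overall_elongation_rate(rates, small_contexts)
        free = MinimizationProblem(
            in_vitro=rates, contexts=small_contexts, v_target=v_target,
            kon_in_vivo=rates.kon, starts=4, seed=4,
        )
        unconstrained = deduce_in_vivo_rates(free)
        # pick the most-shifted coordinate and forbid most of its shift
        name = max(unconstrained.delta_min.deltas, key=lambda n: abs(unconstrained.delta_min[n]))
        cap = 0.25 * abs(unconstrained.delta_min[name])
        bounded = MinimizationProblem(
            in_vitro=rates, contexts=small_contexts, v_target=v_target,
            kon_in_vivo=rates.kon, bounds={name: (-cap, cap)}, starts=4, seed=4,
        )
        result = deduce_in_vivo_rates(bounded)
        assert name in result.boundary_flags
        assert abs(result.delta_min[name]) <= cap + 1e-9

    def test_reference_translation_invariance(self, small_fixture, small_contexts):
        # deducing from an identical second assay gives identical rates
        rates = small_fixture.rates
        v_target = 1.2 * overall_elongation_rate(rates, small_contexts)
        kwargs = dict(contexts=small_contexts, v_target=v_target,
                      kon_in_vivo=rates.kon, starts=4, seed=5)
        a = deduce_in_vivo_rates(MinimizationProblem(in_vitro=rates, **kwargs))
        b = deduce_in_vivo_rates(MinimizationProblem(in_vitro=rates.with_rates(label="assay A'"), **kwargs))
        for name, value in a.rates_in_vivo:
            assert b.rates_in_vivo[name] == pytest.approx(value, rel=1e-9)

    def test_default_kon_is_54_percent_of_in_vitro(self, small_fixture, small_contexts):
        rates = small_fixture.rates
        problem = MinimizationProblem(
            in_vitro=rates, contexts=small_contexts,
            v_target=overall_elongation_rate(rates, small_contexts),
        )
        assert problem.effective_kon == pytest.approx(0.54 * rates.kon, rel=1e-12)


class TestScaleFactors:
    def test_scale_factors_match_rate_ratios(self, small_fixture, small_contexts):
        rates = small_fixture.rates
        v_target = 1.3 * overall_elongation_rate(rates, small_contexts)
        problem = MinimizationProblem(
            in_vitro=rates, contexts=small_contexts, v_target=v_target,
            kon_in_vivo=rates.kon, starts=4, seed=6,
        )
        result = deduce_in_vivo_rates(problem)
        report = scale_factor_report(result)
        for name, factor in report.items():
            assert factor == pytest.approx(
                result.rates_in_vivo[name] / rates[name], rel=1e-12
            )
            assert factor == pytest.approx(math.exp(result.delta_min[name]), rel=1e-12)
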