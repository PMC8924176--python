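import numpy as np
import pytest

from rloopkinetics import (MismatchPattern, ON_TARGET, ParameterSet,
                           QuantityKind, RawMeasurement, SAConfig,
                           average_over_mismatch_types, chi_squared,
                           collect_near_equivalent, make_chi2_cost,
                           simulated_annealing)
from rloopkinetics.experiments import MeasurementRecord, predict_log10_batch
from rloopkinetics.training import SAResult, initial_parameter_vector


def raw(seq, pattern, value, error, physical=True):
    return RawMeasurement(sequence_id=seq, pattern=MismatchPattern(pattern),
                          log10_value=value, log10_error=error,
                          physical=physical)


class TestAveraging:
    def test_single_row_passes_through(self):
        out = average_over_mismatch_types(
            [raw("a", (3,), -1.25, 0.4)], QuantityKind.CLEAVAGE_RATE)
        assert len(out) == 1
        assert out[0].log10_value == -1.25
        assert out[0].log10_error == pytest.approx(0.4)

    def test_equal_errors_reduce_to_sample_mean(self):
        rows = [raw(f"s{i}", (5,), v, 0.3) for i, v in enumerate([1.0, 3.0])]
        out = average_over_mismatch_types(rows, QuantityKind.CLEAVAGE_RATE)
        assert out[0].log10_value == pytest.approx(2.0)

    def test_inverse_variance_weighted_mean(self):
        # weights 1 and 1/4: (1*1.0 + 0.25*3.0) / 1.25 = 1.4
        rows = [raw("a", (2, 9), 1.0, 1.0), raw("b", (2, 9), 3.0, 2.0)]
        out = average_over_mismatch_types(rows, QuantityKind.CLEAVAGE_RATE)
        assert out[0].log10_value == pytest.approx(1.4)
        assert out[0].log10_error == pytest.approx(np.sqrt(1.0 / 1.25))

    def test_non_physical_rows_excluded(self):
        rows = [raw("a", (7,), 1.0, 0.5), raw("b", (7,), 9.0, 0.5,
                                              physical=False)]
        out = average_over_mismatch_types(rows, QuantityKind.CLEAVAGE_RATE)
        assert out[0].log10_value == pytest.approx(1.0)

    def test_fully_excluded_pattern_dropped_with_warning(self):
        rows = [raw("a", (7,), 1.0, 0.5, physical=False),
                raw("b", (), 0.0, 0.5)]
        with pytest.warns(RuntimeWarning, match="dropped"):
            out = average_over_mismatch_types(rows, QuantityKind.CLEAVAGE_RATE)
        assert [r.pattern for r in out] == [ON_TARGET]


class TestChiSquared:
    def _tables_from_predictions(self, params, patterns, kind, deviation=0.0,
                                 error=0.5):
        preds = predict_log10_batch(params, patterns, kind)
        return [MeasurementRecord(pattern=p, kind=kind,
                                  log10_value=float(v) - deviation,
                                  log10_error=error)
                for p, v in zip(patterns, preds)]

    def test_zero_at_perfect_predictions(self, params):
        pats = [ON_TARGET, MismatchPattern((3,)), MismatchPattern((3, 15))]
        clv = self._tables_from_predictions(params, pats,
                                            QuantityKind.CLEAVAGE_RATE)
        ka = self._tables_from_predictions(params, pats,
                                           QuantityKind.ASSOCIATION_CONSTANT)
        assert chi_squared(params, clv, ka) == pytest.approx(0.0, abs=1e-16)

    def test_single_term_is_weighted_square(self, params):
        d, e = 0.7, 0.25
        clv = self._tables_from_predictions(params, [ON_TARGET],
                                            QuantityKind.CLEAVAGE_RATE,
                                            deviation=d, error=e)
        assert chi_squared(params, clv, []) == pytest.approx((d / e) ** 2,
                                                             rel=1e-9)

    def test_group_weights_one_twentieth_one_190th(self, params):
        """On-target, single- and double-mismatch groups enter with weights
        1, 1/20 and 1/190: unit deviations at unit error sum accordingly."""
        pats = [ON_TARGET, MismatchPattern((4,)), MismatchPattern((4, 18))]
        clv = self._tables_from_predictions(params, pats,
                                            QuantityKind.CLEAVAGE_RATE,
                                            deviation=1.0, error=1.0)
        expected = 1.0 + 1.0 / 20.0 + 1.0 / 190.0
        assert chi_squared(params, clv, []) == pytest.approx(expected,
                                                             rel=1e-9)

    def test_order_invariance(self, params, rng):
        pats = [ON_TARGET] + [MismatchPattern((i,)) for i in (1, 5, 9)] \
            + [MismatchPattern((2, 11))]
        clv = self._tables_from_predictions(params, pats,
                                            QuantityKind.CLEAVAGE_RATE, 0.3)
        ka = self._tables_from_predictions(params, pats,
                                           QuantityKind.ASSOCIATION_CONSTANT,
                                           0.2)
        base = chi_squared(params, clv, ka)
        perm = list(rng.permutation(len(clv)))
        assert chi_squared(params, [clv[i] for i in perm],
                           [ka[i] for i in perm]) == pytest.approx(base,
                                                                   rel=1e-12)

    def test_more_than_two_mismatches_rejected(self, params):
        bad = self._tables_from_predictions(params,
                                            [MismatchPattern((1, 2, 3))],
                                            QuantityKind.CLEAVAGE_RATE)
        with pytest.raises(ValueError, match="<=2"):
            chi_squared(params, bad, [])

    def test_compiled_cost_matches_reference(self, params, rng):
        pats = [ON_TARGET] + [MismatchPattern((i,)) for i in range(1, 21)] \
            + [MismatchPattern((3, 15)), MismatchPattern((1, 2))]
        clv = self._tables_from_predictions(params, pats,
                                            QuantityKind.CLEAVAGE_RATE, 0.4)
        ka = self._tables_from_predictions(params, pats,
                                           QuantityKind.ASSOCIATION_CONSTANT,
                                           0.1)
        fast = make_chi2_cost(clv, ka, fast=True)
        ref = make_chi2_cost(clv, ka, fast=False)
        for _ in range(3):
            theta = params.to_vector() + rng.uniform(-0.5, 0.5, 44)
            assert fast(theta) == pytest.approx(ref(theta), rel=1e-4)


class TestSimulatedAnnealing:
    BOWL_CONFIG = SAConfig(cooling_rate=0.85, batch_size=200,
                           stop_rel_tol=1e-4,
                           temperature_floor_fraction=1e-3, seed=11,
                           max_temperature_steps=400)

    def test_quadratic_bowl_recovery(self, rng):
        """Convex sanity case: recover the minimum of a 44-d paraboloid to
        0.05 per coordinate."""
        target = rng.uniform(-2, 2, 44)

        def cost(x):
            return float(np.sum((x - target) ** 2))

        res = simulated_annealing(cost, target + rng.uniform(-1, 1, 44),
                                  self.BOWL_CONFIG)
        np.testing.assert_array_less(np.abs(res.params.to_vector() - target),
                                     0.05)

    def test_exponential_cooling_schedule(self, rng):
        target = np.zeros(44)
        res = simulated_annealing(lambda x: float(np.sum(x * x)),
                                  rng.uniform(-1, 1, 44), self.BOWL_CONFIG)
        ratios = res.temperatures[1:] / res.temperatures[:-1]
        np.testing.assert_allclose(ratios, self.BOWL_CONFIG.cooling_rate,
                                   rtol=1e-12)

    def test_seeded_runs_are_bit_reproducible(self, rng):
        target = rng.uniform(-1, 1, 44)

        def cost(x):
            return float(np.sum((x - target) ** 2))

        cfg = SAConfig(cooling_rate=0.6, batch_size=50, stop_rel_tol=1e-3,
                       temperature_floor_fraction=0.05, seed=21,
                       max_temperature_steps=60)
        x0 = rng.uniform(-2, 2, 44)
        r1 = simulated_annealing(cost, x0, cfg)
        r2 = simulated_annealing(cost, x0, cfg)
        np.testing.assert_array_equal(r1.params.to_vector(),
                                      r2.params.to_vector())
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_non_finite_initial_cost_rejected(self):
        with pytest.raises(ValueError):
            simulated_annealing(lambda x: float("nan"), np.zeros(44),
                                self.BOWL_CONFIG)

    def test_initial_vector_respects_documented_ranges(self, rng):
        for _ in range(5):
            x = initial_parameter_vector(rng)
            p = ParameterSet.from_vector(x)
            assert -10 <= p.F0_ref <= 0
            assert np.all((-5 <= p.eps) & (p.eps <= 5))
            assert np.all((0 <= p.delta_eps) & (p.delta_eps <= 10))


class TestEnsemble:
    @staticmethod
    def _result(cost):
        return SAResult(params=ParameterSet.from_vector(np.full(44, cost)),
                        cost=cost, trace=np.array([cost]),
                        temperatures=np.array([1.0]), n_evaluations=1,
                        converged=True)

    def test_single_run_kept(self):
        ensemble, summary = collect_near_equivalent([self._result(5.0)])
        assert len(ensemble) == 1 and summary["n_kept"] == 1

    def test_15_percent_threshold(self):
        runs = [self._result(c) for c in (10.0, 11.0, 12.0)]
        ensemble, summary = collect_near_equivalent(runs)
        assert [r.cost for r in ensemble] == [10.0, 11.0]
        assert summary["n_runs"] == 3 and summary["n_kept"] == 2

    def test_spread_summary_envelope(self):
        runs = [self._result(c) for c in (10.0, 10.5)]
        _, summary = collect_near_equivalent(runs)
        np.testing.assert_allclose(summary["min"], 10.0)
        np.testing.assert_allclose(summary["max"], 10.5)
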