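import math

import numpy as np
import pytest

from ppfc.coefficients import PeriodicCoefficient
from ppfc.fixtures import FixtureSpec, random_model
from ppfc.model import COEFFICIENT_NAMES, DelaySet, ModelParameters
from ppfc.permanence import (
    compute_bounds,
    control_lower_bounds,
    control_upper_bounds,
    evaluate_H1_H10,
    predator_upper_thresholds,
    prey_upper_bounds,
)

TOL = 5e-4  # published constants carry 4 decimals


def constant_model(**overrides):
    """All-constant model (value 1 unless overridden), no delays."""
    values = {name: 1.0 for name in COEFFICIENT_NAMES}
    values.update(overrides)
    coefs = {
        n: PeriodicCoefficient(constant_term=v, period=1.0)
        for n, v in values.items()
    }
    return ModelParameters(coefs, DelaySet(), omega=1.0)


class TestPublishedConstants:
    """The reference parameter set reproduces the published constants."""

    def test_prey_upper_bounds(self, example1_bounds):
        assert example1_bounds.M1 == pytest.approx(2.6150, abs=TOL)
        assert example1_bounds.M2 == pytest.approx(2.5180, abs=TOL)

    def test_control_upper_bounds(self, example1_bounds):
        # N1..N3 as recomputed from their defining formulas (the published
        # 2.3370 / 2.5175 / 2.3370 are inconsistent with those formulas,
        # while every downstream published value matches these)
        assert example1_bounds.N1 == pytest.approx(2.3323, abs=TOL)
        assert example1_bounds.N2 == pytest.approx(2.5140, abs=TOL)
        assert example1_bounds.N3 == pytest.approx(20.5 / 9.0, abs=TOL)
        assert example1_bounds.N4 == pytest.approx(2.2105, abs=TOL)

    def test_predator_thresholds(self, example1_bounds):
        assert example1_bounds.M3_star == pytest.approx(1.8619, abs=TOL)
        assert example1_bounds.M4_star == pytest.approx(1.9186, abs=TOL)
        assert example1_bounds.m3_star == pytest.approx(0.32088, abs=TOL)
        assert example1_bounds.m4_star == pytest.approx(0.34504, abs=TOL)

    def test_prey_lower_bounds(self, example1_bounds):
        assert example1_bounds.m1 == pytest.approx(1.8600, abs=TOL)
        assert example1_bounds.m2 == pytest.approx(1.7702, abs=TOL)

    def test_control_lower_bounds(self, example1_bounds):
        assert example1_bounds.n3 == pytest.approx(1.8388, abs=TOL)
        assert example1_bounds.n4 == pytest.approx(1.8004, abs=TOL)

    def test_criterion_values(self, example1_criteria):
        expected = {
            "H1": 8.6633, "H2": 9.1895, "H3": 12.3367, "H4": 12.8105,
            "H5": 78.3834, "H6": 82.1211, "H7": 10.6416, "H8": 11.1391,
            "H9": 7.5122, "H10": 8.0712,
        }
        by_name = {c.name: c for c in example1_criteria}
        for name, value in expected.items():
            assert by_name[name].value == pytest.approx(value, abs=TOL), name
            assert by_name[name].satisfied

    def test_all_ten_satisfied(self, example1_criteria):
        assert all(c.satisfied for c in example1_criteria)


class TestClosedFormLimits:
    def test_logistic_limit_M1(self):
        # r1 = a11 = 1, tau11 = 0: the carrying bound is exactly 1
        m = constant_model()
        M1, M2 = prey_upper_bounds(m)
        assert M1 == pytest.approx(1.0)
        assert M2 == pytest.approx(1.0)

    def test_decoupled_control_N1(self):
        m = constant_model(q1=1e-300)  # q effectively 0, keeps positivity
        N1, *_ = control_upper_bounds(m, M1=1.0, M2=1.0)
        assert N1 == pytest.approx(1.0)

    def test_decoupled_control_n3(self):
        m = constant_model(q3=1e-300)
        _, _, n3, _ = control_lower_bounds(m, m1=1.0, m2=1.0, M3=1.0, M4=1.0)
        assert n3 == pytest.approx(1.0)

    def test_M3_star_algebraic_cancellation(self):
        # k3 -> 0, a32 -> 0, a31 = 2 r3: threshold collapses to M1/b13^l
        m = constant_model(k3=1e-300, a32=1e-300, a31=2.0, r3=1.0, b13=4.0)
        M1 = 3.0
        M3_star, _, h1, _, h3, _ = predator_upper_thresholds(m, M1, N3=0.0, N4=0.0)
        assert h1 == pytest.approx(1.0)
        assert M3_star == pytest.approx(M1 / 4.0)

    def test_H3_with_matched_gain_and_death(self):
        # a31 = r3 makes the H3 expression collapse to a32^m + k3^m N3 > 0
        m = constant_model(a31=1.0, r3=1.0, a32=0.3, k3=0.2)
        _, _, _, _, h3, _ = predator_upper_thresholds(m, M1=1.0, N3=2.0, N4=1.0)
        assert h3 == pytest.approx(0.3 + 0.2 * 2.0)

    def test_H1_violation_reported_not_raised(self):
        # huge control feedback makes the predator-3 margin negative
        m = constant_model(k3=100.0)
        crits, bounds = evaluate_H1_H10(m)
        by_name = {c.name: c for c in crits}
        assert not by_name["H1"].satisfied
        assert bounds.M3_star is None
        assert not bounds.complete


class TestStructuralProperties:
    def test_M1_monotone_in_growth_and_competition(self, rng):
        """M1 increases with the top growth rate, decreases with the
        competition floor (finite-difference probes)."""
        for _ in range(20):
            r1 = float(rng.uniform(0.5, 30.0))
            a11 = float(rng.uniform(0.5, 15.0))
            tau = float(rng.uniform(0.0, 0.02))
            delays = DelaySet(tau11=tau)
            def M1_of(r, a):
                m = constant_model(r1=r, a11=a)
                m = ModelParameters(m.coefficients, delays, 1.0)
                return prey_upper_bounds(m)[0]
            base = M1_of(r1, a11)
            assert M1_of(r1 * 1.01, a11) > base
            assert M1_of(r1, a11 * 1.01) < base

    def test_ordering_chain_on_random_fixtures(self):
        """Whenever H1-H10 hold, the starred thresholds are ordered:
        m3* <= M3* and m4* <= M4*."""
        checked = 0
        for seed in range(40):
            params = random_model(FixtureSpec(seed=seed))
            crits, bounds = evaluate_H1_H10(params)
            if not all(c.satisfied for c in crits):
                continue
            checked += 1
            assert 0 < bounds.m3_star <= bounds.M3_star
            assert 0 < bounds.m4_star <= bounds.M4_star
            assert 0 < bounds.m1 <= bounds.M1
            assert 0 < bounds.m2 <= bounds.M2
        assert checked >= 10  # the generator targets the permanent regime

    def test_slack_widens_the_box(self, example1):
        tight = compute_bounds(example1)
        wide = compute_bounds(example1, slack=0.1)
        assert wide.M3 > tight.M3
        assert wide.m3 < tight.m3
        assert wide.M3_star == pytest.approx(tight.M3_star)
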