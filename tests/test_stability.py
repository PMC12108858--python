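import math

import pytest

from ppfc.coefficients import PeriodicCoefficient
from ppfc.fixtures import FixtureSpec, random_model
from ppfc.model import COEFFICIENT_NAMES, DelaySet, ModelParameters
from ppfc.permanence import compute_bounds
from ppfc.stability import evaluate_A, evaluate_B, evaluate_H11_H18

TOL = 5e-4


# ---------------------------------------------------------------------------
# independent oracle: enumerate every summand of each margin as a list and
# fsum it; shares nothing with the production evaluator but the formulas


def _margin_terms(params, b):
    s = {n: params.sup(n) for n in COEFFICIENT_NAMES}
    l = {n: params.inf(n) for n in COEFFICIENT_NAMES}
    t = params.delays.as_dict()
    D13 = l["b13"] * b.m3 + b.m1
    D14 = l["b14"] * b.m4 + b.m1
    D23 = l["b23"] * b.m3 + b.m2
    D24 = l["b24"] * b.m4 + b.m2
    load1 = (s["r1"] + s["a11"] * b.M1 + s["a12"] * b.M2
             + s["a13"] * b.M3 / D13 + s["a14"] * b.M4 / D14 + s["k1"] * b.N1)
    load2 = (s["r2"] + s["a22"] * b.M2 + s["a21"] * b.M1
             + s["a23"] * b.M3 / D23 + s["a24"] * b.M4 / D24 + s["k2"] * b.N2)

    A1 = [
        l["a11"], -s["a21"], -s["q1"],
        -(s["a11"] * t["tau11"] + s["a21"] * t["tau21"]) * load1,
        -(b.M1 * s["a11"] * t["tau11"] + b.M1 * s["a21"] * t["tau21"] + 1
          + s["b13"]) * s["a13"] * b.M3 / D13 ** 2,
        -(b.M1 * s["a11"] * t["tau11"] + b.M1 * s["a21"] * t["tau21"] + 1
          + s["b14"]) * s["a14"] * b.M4 / D14 ** 2,
        -b.M1 * s["a11"] ** 2 * t["tau11"],
        -b.M2 * s["a21"] * s["a12"] * t["tau12"],
        -b.M2 * s["a21"] * s["a22"] * t["tau22"],
        -b.M1 * s["a21"] * s["a11"] * t["tau21"],
        -s["a34"] * t["tau34"] * s["a41"] * s["b14"] * b.M4 ** 2 / D14 ** 2,
        -s["a43"] * t["tau43"] * s["a31"] * s["b13"] * b.M3 ** 2 / D13 ** 2,
    ]
    A2 = [
        l["a22"], -s["a12"], -s["q2"],
        -(s["a12"] * t["tau12"] + s["a22"] * t["tau22"]) * load2,
        -(b.M2 * s["a12"] * t["tau12"] + b.M2 * s["a22"] * t["tau22"] + 1
          + s["b23"]) * s["a23"] * b.M3 / D23 ** 2,
        -(b.M2 * s["a12"] * t["tau12"] + b.M2 * s["a22"] * t["tau22"] + 1
          + s["b24"]) * s["a24"] * b.M4 / D24 ** 2,
        -b.M1 * s["a12"] * s["a11"] * t["tau11"],
        -b.M2 * s["a12"] * s["a22"] * t["tau12"],
        -b.M2 * s["a22"] ** 2 * t["tau22"],
        -b.M1 * s["a12"] * s["a21"] * t["tau21"],
        -s["a34"] * t["tau34"] * s["a42"] * s["b24"] * b.M4 ** 2 / D24 ** 2,
        -s["a43"] * t["tau43"] * s["a32"] * s["b23"] * b.M3 ** 2 / D23 ** 2,
    ]
    A3 = [
        l["a31"] * l["b13"] * b.m2 / (s["b13"] * b.M3 + b.M1) ** 2,
        l["a32"] * l["b23"] * b.m2 / (s["b23"] * b.M3 + b.M2) ** 2,
        -s["a34"] * t["tau34"] * s["a43"] * b.M4,
        -s["a43"], -s["q3"],
        -s["a13"] * b.M1 / D13 ** 2,
        -s["a13"] * b.M1 ** 2 * (s["a11"] * t["tau11"] + s["a21"] * t["tau21"]) / D13 ** 2,
        -s["a43"] * t["tau43"] * s["a31"] * s["b13"] * b.M1 * b.M3 / D13 ** 2,
        -s["a23"] * b.M2 ** 2 * s["a12"] * t["tau12"] / D23 ** 2,
        -s["a43"] * t["tau43"] * s["a32"] * s["b23"] * b.M2 * b.M3 / D23 ** 2,
        -s["a23"] * b.M2 / D23 ** 2,
        -s["a23"] * b.M2 ** 2 * s["a22"] * t["tau22"] / D23 ** 2,
        -s["a43"] * t["tau43"] * (s["r3"] + s["a31"] * b.M1 / D13
                                  + s["a32"] * b.M2 / D23 + s["a34"] * b.M4
                                  + s["k3"] * b.N3),
    ]
    A4 = [
        l["a41"] * l["b14"] * b.m2 / (s["b14"] * b.M4 + b.M1) ** 2,
        l["a42"] * l["b24"] * b.m2 / (s["b24"] * b.M4 + b.M2) ** 2,
        -s["a34"],
        -s["a43"] * t["tau43"] * s["a34"] * b.M3,
        -s["q4"],
        -s["a14"] * b.M1 / D14 ** 2,
        -s["a14"] * b.M1 ** 2 * s["a11"] * t["tau11"] / D14 ** 2,
        -s["a14"] * b.M1 ** 2 * s["a21"] * t["tau21"] / D14 ** 2,
        -s["a34"] * t["tau34"] * s["a41"] * s["b14"] * b.M1 * b.M4 / D14 ** 2,
        -s["a24"] * b.M2 ** 2 * (s["a12"] * t["tau12"] + s["a22"] * t["tau22"]) / D24 ** 2,
        -s["a34"] * t["tau34"] * s["a42"] * s["b24"] * b.M2 * b.M4 / D24 ** 2,
        -s["a24"] * b.M2 / D24 ** 2,
        -s["a34"] * t["tau34"] * (s["r4"] + s["a41"] * b.M1 / D14
                                  + s["a42"] * b.M2 / D24 + s["a43"] * b.M3
                                  + s["k4"] * b.N4),
    ]
    B1 = [l["f1"], -s["k1"] * (1 + b.M1 * s["a11"] * t["tau11"]),
          -b.M1 * s["k1"] * s["a21"] * t["tau21"]]
    B2 = [l["f2"], -b.M2 * s["k2"] * s["a12"] * t["tau12"],
          -s["k2"] * (1 + b.M2 * s["a22"] * t["tau22"])]
    B3 = [l["f3"], -s["k3"], -s["a43"] * t["tau43"] * s["k3"] * b.M3]
    B4 = [l["f4"], -s["k4"], -s["a34"] * t["tau34"] * s["k4"] * b.M4]
    return [A1, A2, A3, A4], [B1, B2, B3, B4]


class TestPublishedMargins:
    def test_A_values(self, example1, example1_bounds):
        A = evaluate_A(example1, example1_bounds)
        assert A[0] == pytest.approx(7.8508, abs=TOL)
        assert A[1] == pytest.approx(7.7023, abs=TOL)
        # the published A3 = 1.4256 is a last-digit rounding of 1.42571
        assert A[2] == pytest.approx(1.4257, abs=TOL)
        assert A[3] == pytest.approx(1.4528, abs=TOL)

    def test_B_values(self, example1, example1_bounds):
        B = evaluate_B(example1, example1_bounds)
        assert B[0] == pytest.approx(9.4382, abs=TOL)
        assert B[1] == pytest.approx(8.9257, abs=TOL)
        assert B[2] == pytest.approx(8.9400, abs=TOL)
        assert B[3] == pytest.approx(9.4500, abs=TOL)

    def test_full_verdict(self, example1):
        report = evaluate_H11_H18(example1)
        assert report.prerequisites_ok
        assert all(c.satisfied for c in report.criteria)
        assert report.verdict


class TestTermByTermOracle:
    def test_margins_match_independent_summation(self):
        """An independent enumeration of every summand agrees with the
        production evaluator to near machine precision."""
        checked = 0
        for seed in range(60):
            params = random_model(FixtureSpec(seed=seed))
            bounds = compute_bounds(params)
            if not bounds.complete:
                continue
            checked += 1
            A = evaluate_A(params, bounds)
            B = evaluate_B(params, bounds)
            A_terms, B_terms = _margin_terms(params, bounds)
            for i in range(4):
                assert A[i] == pytest.approx(math.fsum(A_terms[i]), abs=1e-12)
                assert B[i] == pytest.approx(math.fsum(B_terms[i]), abs=1e-12)
        assert checked >= 50


class TestStructuralProperties:
    def test_A1_decreases_in_control_gain(self, example1, example1_bounds):
        """Raising the control feedback q1 lowers A1 one-for-one."""
        A1_base = evaluate_A(example1, example1_bounds)[0]
        coefs = dict(example1.coefficients)
        coefs["q1"] = PeriodicCoefficient(10.0, period=2.0)
        bumped = ModelParameters(coefs, example1.delays, example1.omega)
        report = evaluate_H11_H18(bumped)
        A1_new = report.A[0]
        # drops at least one-for-one in q1^m (indirect N1 effects only
        # push it further down)
        assert A1_new <= A1_base - (10.0 - example1.sup("q1")) + 1e-9
        assert A1_new < 0
        assert not report.verdict

    def test_A1_nonincreasing_in_delays(self, example1, example1_bounds):
        import dataclasses

        A1_base = evaluate_A(example1, example1_bounds)[0]
        for name in ("tau11", "tau21", "tau12", "tau22", "tau34", "tau43"):
            delays = dataclasses.replace(
                example1.delays, **{name: getattr(example1.delays, name) * 3.0}
            )
            bumped = ModelParameters(example1.coefficients, delays, example1.omega)
            # keep the permanence box fixed: the probe isolates the direct
            # delay dependence of the margin expression
            A1_new = evaluate_A(bumped, example1_bounds)[0]
            assert A1_new <= A1_base + 1e-12, name

    def test_diagonal_model_margin(self):
        """With every coupling, control and delay off, A1 collapses to the
        self-damping floor a11^l."""
        from ppfc.permanence import PermanenceBounds

        values = {name: 1e-12 for name in COEFFICIENT_NAMES}
        for name in ("r1", "r2", "r3", "r4", "a11", "a22", "e1", "e2", "e3",
                     "e4", "f1", "f2", "f3", "f4", "b13", "b14", "b23", "b24",
                     "a31", "a41", "d1", "d2", "d3", "d4"):
            values[name] = 1.0
        coefs = {n: PeriodicCoefficient(v, period=1.0) for n, v in values.items()}
        params = ModelParameters(coefs, DelaySet(), omega=1.0)
        ones = {f: 1.0 for f in (
            "M1", "M2", "N1", "N2", "N3", "N4", "M3_star", "M4_star",
            "m1", "m2", "n1", "n2", "n3", "n4", "m3_star", "m4_star",
            "M3", "M4", "m3", "m4")}
        bounds = PermanenceBounds(**ones)
        A = evaluate_A(params, bounds)
        assert A[0] == pytest.approx(params.inf("a11"), abs=1e-6)

    def test_incomplete_bounds_are_rejected(self, example1, example1_bounds):
        import dataclasses

        broken = dataclasses.replace(example1_bounds, m3=None)
        with pytest.raises(ValueError):
            evaluate_A(example1, broken)
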