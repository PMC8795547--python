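"""Experiment drivers: fits, optimizer machinery, exponent tables."""

import math

import numpy as np
import pytest

from selfassembly.experiments import (
    T90Estimate,
    control_anchor,
    estimate_t90,
    fit_power_law,
    minimize_scalar_log,
    nucleation_growth_ratio,
    replicate_seeds,
    theoretical_exponents,
    yield_curve,
)
from selfassembly.kinetics import run_simulation
from selfassembly.lattice import build_geometry
from selfassembly.scenarios import make_dimerization


class TestFitPowerLaw:
    def test_exact_power_law(self):
        S = np.array([8, 16, 32, 64])
        fit = fit_power_law(S, 5.0 * S**2)
        assert fit.exponent == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_noisy_exponent_recovery(self, rng):
        S = np.array([8, 16, 32, 64, 128])
        hits = 0
        for _ in range(100):
            vals = 3.0 * S**-2.0 * np.exp(rng.normal(0, 0.05, S.size))
            fit = fit_power_law(S, vals)
            if abs(fit.exponent + 2.0) <= 3 * fit.stderr:
                hits += 1
        assert hits >= 90  # 3-sigma coverage

    def test_scale_equivariance(self):
        from hypothesis import given, settings, strategies as st

        S = np.array([4, 9, 16, 25])
        vals = 2.0 * S**1.3 * np.array([1.01, 0.98, 1.02, 0.99])
        a = fit_power_law(S, vals)

        @settings(max_examples=25, derandomize=True, deadline=None)
        @given(scale=st.floats(1e-6, 1e6, allow_nan=False))
        def check(scale):
            b = fit_power_law(S, scale * vals)
            assert b.exponent == pytest.approx(a.exponent)
            assert b.stderr == pytest.approx(a.stderr, abs=1e-9)

        check()

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_power_law([2, 4], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_power_law([2, 4, 8], [1.0, -2.0, 3.0])


class TestMinimizer:
    def test_synthetic_unimodal(self):
        x, f, evals = minimize_scalar_log(lambda p: p + 1.0 / p, (0.1, 10.0))
        assert x == pytest.approx(1.0, rel=0.02)
        assert f == pytest.approx(2.0, rel=0.01)
        assert min(evals.values()) <= f * 1.01

    def test_infeasible_everywhere(self):
        x, f, evals = minimize_scalar_log(lambda p: math.inf, (0.1, 10.0))
        assert math.isnan(x) and math.isinf(f)

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            minimize_scalar_log(lambda p: p, (1.0, 0.5))


class TestTheoreticalExponents:
    def test_paper_anchors(self):
        assert theoretical_exponents("jis", 3)["theta"] == pytest.approx(4 / 3)
        assert theoretical_exponents("jis", 1)["theta"] == pytest.approx(2.0)
        rev1 = theoretical_exponents("reversible", 1)
        assert rev1["theta"] == 4.0 and rev1["phi"] == 2.0
        assert theoretical_exponents("dimerization", 1)["phi"] == 2.0
        assert theoretical_exponents("activation", 1)["phi"] == 3.0
        assert theoretical_exponents("reversible", 2)["theta"] == pytest.approx(1.19)
        assert theoretical_exponents("reversible", 3)["theta"] == pytest.approx(0.75)

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            theoretical_exponents("annealing", 1)
        with pytest.raises(ValueError):
            theoretical_exponents("jis", 4)

    def test_anchors_positive(self):
        for scen in ("dimerization", "activation", "reversible", "jis"):
            for d in (1, 2, 3):
                assert control_anchor(scen, 27, d) > 0


class TestEstimateT90:
    def test_deterministic_given_seed(self):
        g = build_geometry(1, 8)
        cfg = make_dimerization(g, 0.02, 200)
        a = estimate_t90(cfg, 3, seed=5)
        b = estimate_t90(cfg, 3, seed=5)
        np.testing.assert_array_equal(a.t90s, b.t90s)
        assert a.seeds == b.seeds

    def test_censoring_marks_infeasible(self):
        g = build_geometry(1, 32)
        cfg = make_dimerization(g, 1.0, 100)  # kinetic trap
        est = estimate_t90(cfg, 4, seed=1, max_time=1e5)
        assert est.n_failed == 4
        assert not est.feasible
        assert math.isnan(est.mean)

    def test_replicate_count_precondition(self):
        g = build_geometry(1, 4)
        cfg = make_dimerization(g, 0.1, 10)
        with pytest.raises(ValueError):
            estimate_t90(cfg, 0, seed=1)


def test_replicate_seeds_are_deterministic_and_bounded():
    a = replicate_seeds(123, 16)
    b = replicate_seeds(123, 16)
    np.testing.assert_array_equal(a, b)
    assert (a < 2**31).all()
    assert len(set(a.tolist())) == 16


def test_yield_curve_transition():
    """1D dimerization yield goes from ~1 at slow nucleation to ~0 at
    mu = nu, with the 90% transition identified in between."""
    g = build_geometry(1, 32)
    grid = np.geomspace(1e-4, 1.0, 7)
    res = yield_curve("dimerization", g, grid, 3, seed=9, N=200)
    table = res.table
    assert table["yield_mean"].iloc[0] > 0.9
    assert table["yield_mean"].iloc[-1] < 0.1
    assert grid.min() <= res.transition <= grid.max()
    # single-point grid gives a single row
    single = yield_curve("dimerization", g, [1e-3], 2, seed=9, N=100)
    assert len(single.table) == 1


def test_find_optimal_soundness():
    """The reported optimum tracks the best probed feasible evaluation and
    its control value lies inside the scanned bounds."""
    from selfassembly.experiments import find_optimal

    g = build_geometry(1, 16)
    res = find_optimal("dimerization", g, n_replicates=4, seed=13, N=300)
    ev = res.evaluations[res.evaluations["feasible"]]
    best_probed = ev["t90_mean"].min()
    assert 0.7 * best_probed <= res.t90min <= 1.3 * best_probed
    assert ev["control"].min() <= res.control <= ev["control"].max()
    # optimal nucleation rate sits slightly below the 90%-yield transition
    assert res.control < 1.0


def test_nucleation_growth_ratio():
    g = build_geometry(1, 16)
    cfg = make_dimerization(g, 16.0**-2, 500)
    traj = run_simulation(cfg, seed=3)
    r = nucleation_growth_ratio(traj)
    assert r == traj.event_counts["dimerize"] / traj.event_counts["attach"]

    class Empty:
        def attachment_events(self):
            return 0

        def nucleation_events(self):
            return 0

    assert math.isnan(nucleation_growth_ratio(Empty()))
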