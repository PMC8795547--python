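"""Observational equivalence of the compiled engines and the reference SSA.

The compiled ring/lattice engines must reproduce the reference loop's
statistics (they share the reaction rules but none of the code), and every
engine must conserve mass exactly.
"""

import math

import numpy as np
import pytest

from selfassembly.kinetics import run_simulation
from selfassembly.lattice import build_geometry
from selfassembly.scenarios import (
    make_activation,
    make_dimerization,
    make_jis,
    make_reversible,
)


def mean_sem(vals):
    vals = np.asarray(vals, dtype=float)
    return vals.mean(), vals.std(ddof=1) / math.sqrt(len(vals))


def assert_statistically_equal(a_vals, b_vals, label, sigma=4.0):
    ma, sa = mean_sem(a_vals)
    mb, sb = mean_sem(b_vals)
    z = abs(ma - mb) / math.hypot(sa, sb)
    assert z < sigma, f"{label}: {ma:.4g} vs {mb:.4g} (z = {z:.2f})"


N_SEEDS = 16


class TestRingVsReference:
    def test_dimerization_t90(self):
        g = build_geometry(1, 6)
        cfg = make_dimerization(g, 0.05, 60)
        ring = [run_simulation(cfg, seed=s, engine="ring").t90
                for s in range(N_SEEDS)]
        ref = [run_simulation(cfg, seed=1000 + s, engine="reference").t90
               for s in range(N_SEEDS)]
        assert not any(math.isnan(x) for x in ring + ref)
        assert_statistically_equal(ring, ref, "T90 ring vs reference")

    def test_reversible_t90(self):
        g = build_geometry(1, 6)
        cfg = make_reversible(g, 44.0, 40)  # delta1 ~ 0.08, delta2 ~ 0
        ring = [run_simulation(cfg, seed=s, engine="ring",
                               stop={"max_time": 1e6}).t90
                for s in range(N_SEEDS)]
        ref = [run_simulation(cfg, seed=1000 + s, engine="reference",
                              stop={"max_time": 1e6}).t90
               for s in range(N_SEEDS)]
        assert_statistically_equal(ring, ref, "reversible T90")

    def test_jis_final_yield(self):
        g = build_geometry(1, 6)
        cfg = make_jis(g, 20.0, 40)
        ring = [run_simulation(cfg, seed=s, engine="ring",
                               run_until="end").final_yield
                for s in range(N_SEEDS)]
        ref = [run_simulation(cfg, seed=1000 + s, engine="reference",
                              run_until="end").final_yield
               for s in range(N_SEEDS)]
        assert_statistically_equal(ring, ref, "JIS final yield")

    def test_activation_final_yield(self):
        g = build_geometry(1, 4)
        cfg = make_activation(g, 5e-3, 60)
        ring = [run_simulation(cfg, seed=s, engine="ring",
                               run_until="end").final_yield
                for s in range(N_SEEDS)]
        ref = [run_simulation(cfg, seed=1000 + s, engine="reference",
                              run_until="end").final_yield
               for s in range(N_SEEDS)]
        assert_statistically_equal(ring, ref, "activation final yield")


class TestLatticeVsReference:
    def test_dimerization_t90_2d(self):
        g = build_geometry(2, 2)
        cfg = make_dimerization(g, 0.1, 50)
        lat = [run_simulation(cfg, seed=s, engine="lattice").t90
               for s in range(N_SEEDS)]
        ref = [run_simulation(cfg, seed=1000 + s, engine="reference").t90
               for s in range(N_SEEDS)]
        assert_statistically_equal(lat, ref, "2D T90 lattice vs reference")

    def test_reversible_yield_2d(self):
        g = build_geometry(2, 3)
        cfg = make_reversible(g, 41.0, 30)  # delta1 ~ 1.5, delta2 ~ 0
        stop = {"max_time": 150.0}
        lat = [run_simulation(cfg, seed=s, engine="lattice", stop=stop,
                              run_until="end").final_yield
               for s in range(N_SEEDS)]
        ref = [run_simulation(cfg, seed=1000 + s, engine="reference",
                              stop=stop, run_until="end").final_yield
               for s in range(N_SEEDS)]
        assert_statistically_equal(lat, ref, "2D reversible yield")

    def test_jis_final_yield_3d(self):
        g = build_geometry(3, 2)
        cfg = make_jis(g, 10.0, 30)
        lat = [run_simulation(cfg, seed=s, engine="lattice",
                              run_until="end").final_yield
               for s in range(N_SEEDS)]
        ref = [run_simulation(cfg, seed=1000 + s, engine="reference",
                              run_until="end").final_yield
               for s in range(N_SEEDS)]
        assert_statistically_equal(lat, ref, "3D JIS yield")


class TestEngineMassConservation:
    @pytest.mark.parametrize("maker,kwargs", [
        (make_dimerization, {"mu_over_nu": 0.02}),
        (make_reversible, {"E_B": 40.0}),
    ])
    def test_ring_mass_audit(self, maker, kwargs):
        g = build_geometry(1, 12)
        N = 300
        key = "mu_over_nu" if maker is make_dimerization else "E_B"
        cfg = maker(g, kwargs[key], N)
        traj = run_simulation(cfg, seed=7, run_until="end",
                              stop={"max_time": 2e4})
        active, unsup, M, completed = traj.final_state
        arc_mass = sum(M[a, k] * k for a in range(g.S) for k in range(g.S))
        assert active.sum() + unsup.sum() + arc_mass + g.S * completed == g.S * N
        assert (active >= 0).all()

    def test_lattice_mass_audit(self):
        g = build_geometry(2, 4)
        N = 120
        cfg = make_reversible(g, 39.0, N)
        traj = run_simulation(cfg, seed=11, run_until="end",
                              stop={"max_time": 5e3})
        active, occ, size, completed = traj.final_state
        assert active.sum() + int(occ.sum()) + g.S * completed == g.S * N
        assert (active >= 0).all()
        # occupancy rows match the recorded sizes
        assert (occ.sum(axis=1) == size).all()

    def test_lattice_determinism(self):
        g = build_geometry(2, 3)
        cfg = make_dimerization(g, 0.05, 40)
        a = run_simulation(cfg, seed=3, engine="lattice", run_until="end")
        b = run_simulation(cfg, seed=3, engine="lattice", run_until="end")
        np.testing.assert_array_equal(a.times, b.times)
        assert a.n_events == b.n_events
        assert a.final_yield == b.final_yield
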