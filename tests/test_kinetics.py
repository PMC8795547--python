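"""Propensities, the direct SSA step, and the simulation entry point."""

import math

import numpy as np
import pytest

from selfassembly.kinetics import (
    RateConstants,
    compute_propensities,
    detachment_rate,
    run_simulation,
    ssa_step,
)
from selfassembly.lattice import build_geometry
from selfassembly.scenarios import make_activation, make_dimerization
from selfassembly.state import SystemState, apply_event


class TestDetachmentRate:
    def test_irreversible_default_is_zero(self):
        r = RateConstants.create(N=100)
        assert math.isinf(r.E_B)
        for n in (1, 2, 6):
            assert detachment_rate(n, r) == 0.0

    def test_arrhenius_value(self):
        r = RateConstants.create(N=100, C=1.0, nu=1.0, E_B=10.0)
        assert detachment_rate(1, r) == pytest.approx(4.539993e13, rel=1e-6)

    def test_bond_ratio_cancels_prefactor(self):
        r = RateConstants.create(N=7, C=2.5, nu=0.3, E_B=4.0)
        assert detachment_rate(2, r) / detachment_rate(1, r) == pytest.approx(
            math.exp(-4.0)
        )

    def test_unbound_rejected(self):
        r = RateConstants.create(N=10, E_B=5.0)
        with pytest.raises(ValueError):
            detachment_rate(0, r)


class TestPropensities:
    def test_s2_total_dimerization(self):
        g = build_geometry(1, 2)
        N, C, mu = 50, 2.0, 0.7
        rates = RateConstants.create(N=N, C=C, mu=mu)
        st = SystemState.fresh(g, N)
        table = compute_propensities(st, rates, g)
        assert len(table.entries) == 1
        assert table.total == pytest.approx(mu * N * C)

    def test_open_chain_has_two_attachment_entries(self, ring8):
        rates = RateConstants.create(N=5)
        st = SystemState.fresh(ring8, 5)
        apply_event(st, ("dimerize", 3, 4))
        table = compute_propensities(st, rates, ring8)
        att = [e for e in table.entries if e[0] == "attach"]
        assert len(att) == 2
        assert {e[1][1] for e in att} == {2, 5}
        assert all(e[2] == pytest.approx(1.0 * 5 / rates.V) for e in att)

    def test_brute_force_total_on_random_states(self, rng):
        """Table total equals an independently accumulated event-list sum."""
        g = build_geometry(2, 3)
        N = 4
        rates = RateConstants.create(N=N, E_B=2.0, mu=0.6, nu=1.3)
        st = SystemState.fresh(g, N)
        for _ in range(120):
            table = compute_propensities(st, rates, g)
            # independent accumulation from first principles
            expected = 0.0
            for i, j in g.bond_pairs():
                expected += (
                    rates.mu
                    * st.pools.active[i - 1]
                    * st.pools.active[j - 1]
                    / rates.V
                )
            for c in st.clusters:
                for site, b in c.frontier().items():
                    expected += b * rates.nu * st.pools.active[site - 1] / rates.V
                from selfassembly.state import removable_members

                for site, n in removable_members(g, c).items():
                    expected += rates.A * math.exp(-n * rates.E_B)
            assert table.total == pytest.approx(expected, rel=1e-12)
            if not table.entries:
                break
            kind, payload, _ = table.entries[rng.integers(len(table.entries))]
            apply_event(st, (kind, *payload))

    def test_absorbing_state_empty_table(self):
        g = build_geometry(1, 2)
        rates = RateConstants.create(N=3)
        st = SystemState.fresh(g, 3)
        st.pools.active[:] = 0
        st.completed = 3
        assert compute_propensities(st, rates, g).total == 0.0


class TestSSAStep:
    def test_mean_waiting_time(self, ring8, rng):
        rates = RateConstants.create(N=1, mu=0.25)
        st = SystemState.fresh(ring8, 1)
        st.pools.active[:] = 0
        st.pools.active[0] = 1
        st.pools.active[1] = 1
        table = compute_propensities(st, rates, ring8)
        assert len(table.entries) == 1
        a = table.total
        waits = []
        for _ in range(4000):
            _, w = ssa_step(st, table, rng)
            waits.append(w)
        assert np.mean(waits) == pytest.approx(1.0 / a, rel=0.05)

    def test_selection_frequencies(self, ring8, rng):
        rates = RateConstants.create(N=2, mu=1.0)
        st = SystemState.fresh(ring8, 2)
        st.pools.active[:] = 0
        # pair (1,2) weight 1*1 = a; pair (4,5) weight 3 a via counts
        st.pools.active[0] = 1
        st.pools.active[1] = 1
        st.pools.active[3] = 1
        st.pools.active[4] = 3
        table = compute_propensities(st, rates, ring8)
        assert len(table.entries) == 2
        picks = [ssa_step(st, table, rng)[0] for _ in range(10000)]
        frac = np.mean([ev[1:] == (4, 5) for ev in picks])
        assert frac == pytest.approx(0.75, abs=0.02)

    def test_boundary_truncation(self, ring8, rng):
        rates = RateConstants.create(N=1, mu=1e-9)
        st = SystemState.fresh(ring8, 1)
        table = compute_propensities(st, rates, ring8)
        event, wait = ssa_step(st, table, rng, next_boundary=0.5)
        assert event is None and wait == pytest.approx(0.5)

    def test_absorbing_rejected(self, ring8, rng):
        st = SystemState.fresh(ring8, 1)
        st.pools.active[:] = 0
        rates = RateConstants.create(N=1)
        table = compute_propensities(st, rates, ring8)
        with pytest.raises(ValueError):
            ssa_step(st, table, rng)


class TestRunSimulation:
    @pytest.mark.parametrize("engine", ["ring", "reference"])
    def test_determinism(self, engine):
        g = build_geometry(1, 6)
        cfg = make_dimerization(g, 0.05, 50)
        a = run_simulation(cfg, seed=42, engine=engine, run_until="end")
        b = run_simulation(cfg, seed=42, engine=engine, run_until="end")
        assert a.t90 == b.t90
        assert a.n_events == b.n_events
        np.testing.assert_array_equal(a.times, b.times)

    def test_s2_stochastic_matches_closed_form(self):
        """S = 2 dimerization: T90 = 9/(mu C) within 5% at N = 1e4."""
        g = build_geometry(1, 2)
        cfg = make_dimerization(g, 1.0, 10_000)
        t90s = [run_simulation(cfg, seed=s).t90 for s in range(5)]
        assert np.mean(t90s) == pytest.approx(9.0, rel=0.05)

    def test_kinetic_trap_at_default_rates(self):
        """mu = nu leaves a 1D S = 64 system far short of 90% yield."""
        g = build_geometry(1, 64)
        cfg = make_dimerization(g, 1.0, 200)
        traj = run_simulation(cfg, seed=0, run_until="end")
        assert traj.final_yield < 0.5
        assert math.isnan(traj.t90)

    def test_activation_supplies_full_allotment(self):
        """Every copy is activated by the end of its influx window."""
        g = build_geometry(1, 4)
        N = 200
        cfg = make_activation(g, 0.01, N)
        traj = run_simulation(cfg, seed=1, run_until="end", engine="ring")
        active, unsup, M, completed = traj.final_state
        assert traj.event_counts["influx"] > 0
        assert unsup.sum() == 0  # window flush delivered the remainder
        arc_mass = sum(
            M[a, k] * k for a in range(g.S) for k in range(g.S)
        )
        assert active.sum() + arc_mass + g.S * completed == g.S * N

    def test_invalid_stop_criteria(self):
        g = build_geometry(1, 4)
        cfg = make_dimerization(g, 0.1, 10)
        with pytest.raises(ValueError):
            run_simulation(cfg, stop={"max_time": -1.0}, seed=0)
        with pytest.raises(ValueError):
            run_simulation(cfg, seed=0, run_until="sideways")
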