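# selfassembly

Stochastic kinetics of heterogeneous self-assembly under supply and rate
control, with time-complexity analysis.

`N` identical copies of `S` distinct monomer species assemble a fully
addressable target — a 1D ring, 2D sheet or 3D cube of edge length `L`
(`S = L**d`) — by specific binding between neighbouring species in a
well-mixed volume.  Uncontrolled assembly kinetically traps: too many
structures nucleate, deplete the monomer pools, and starve each other.
The package implements four control strategies that avoid the trap —

* **reversible binding** (binding energy `E_B`, Arrhenius detachment
  `delta_n = 1e18 * C * nu * exp(-n*E_B)`),
* **dimerization control** (nucleation barrier `mu/nu < 1`),
* **activation** (constant influx `N*alpha` over a window `1/alpha`),
* **just-in-sequence supply** (species batched in an onion-shell order at
  intervals `Delta_T`, optionally with a 0.9N→1.1N nonstoichiometric ramp)

— and measures, for each, the minimal time `T90min` to assemble 90% of the
possible structures, the optimal control value, and the power laws

    T90min ~ S**theta          (time-complexity exponent theta)
    param_opt ~ S**(-phi)      (control-parameter exponent phi)

via exact Gillespie simulation (numba-compiled engines for 1D rings and
2D/3D lattices, a transparent pure-Python reference loop), a
Becker–Döring-type mean-field integrator as an independent cross-check,
and an experiment layer (replicated `T90` estimation, yield curves,
noisy-objective optimal-control search, log-log exponent fits).

Intended for quantitative self-assembly work: comparing supply-control
protocols for addressable nanostructures (DNA bricks and the like) and for
studying nucleation-growth control in general.

## Worked example

```python
import selfassembly as sa

# a ring of 64 species, 1000 copies each, nucleation-controlled
g = sa.build_geometry(1, 64)
cfg = sa.make_dimerization(g, mu_over_nu=64.0**-2, N=1000)
traj = sa.run_simulation(cfg, seed=1)
print(f"T90 = {traj.t90:.1f}  (events: {traj.n_events})")

# full size series: per-size optimal mu, then power-law fits
res = sa.scaling_experiment("dimerization", 1, [16, 32, 64, 128],
                            n_replicates=10, seed=1, N=1000)
print(res.summary())
```

prints (seed 1):

```
T90 = 644.7  (events: 58428)
scenario dimerization, d = 1
theta_sim = exponent +0.999 ± 0.009 (r² = 0.9998)   (theory anchor 1.0)
phi_sim   = exponent +2.042 ± 0.067 (r² = 0.9989)   (theory anchor 2.0)
```

`T90` is in units of `(C*nu)**-1`.  The fitted `theta ≈ 1` says the
minimal assembly time of nucleation-controlled linear structures grows
linearly with structure size; `phi ≈ 2` says the optimal dimerization rate
must be lowered as `S**-2` — together the quantitative form of the
slow-nucleation principle (about one nucleation per `S` attachments).

The same machinery drives the other scenarios, e.g.
`sa.make_jis(sa.build_geometry(3, 3), delta_T=400.0, N=10_000,
ramp="linear")` for ramped onion-shell supply of a 3×3×3 cube.

A CLI mirrors the library:

```
selfassembly simulate --config run.yaml --seed 1
selfassembly scaling --scenario dimerization --d 1 --sizes 16,32,64,128
selfassembly jis-plan -L 5 --d 2 --delta-t 3.5 --n 100 --ramp linear
selfassembly fixtures --suite analytic --seed 0
```

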