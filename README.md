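# sirsevo

Spatially explicit delayed-SIRS epidemics with an evolving pathogen:
a lattice simulator and analysis toolkit for studying how a
transmission-virulence trade-off *emerges* from spatial self-structuring,
with no physiological constraint imposed.

## The science

Hosts occupy a periodic L x L lattice (Moore neighbourhood, 8 contacts) and
cycle S -> I -> R -> S.  Residence in I and R lasts a fixed time (tau_I,
tau_R): delta-distributed delays, which make the medium excitable and let
infection travel as waves.  Each infected host carries a strain
s = (beta, tau_I) — transmission rate and infection period (the virulence
proxy) — that mutates in small steps at rate mu.  A susceptible site with
infected neighbours Omega_j is infected per sweep with probability
`1 - exp(-dt * sum(beta_n))`, copying one neighbour's strain with
probability proportional to its beta; infected hosts cannot be reinfected
(superinfection exclusion).

On the lattice the base reproductive number is bounded by the neighbourhood
size,

    R0 = 8 (1 - exp(-beta * tau_I)),

and two selection regimes exist.  In the spatially disordered phase,
selection increases R0 without limit — the mean-field runaway that ends in
extinction.  Once spiral waves self-organise, what wins is the *wave
emission frequency* (in 1D, `w_1D = 1/(1/beta + tau_I + tau_R)`), which
*decreases* with tau_I.  Evolution balances the two mechanisms on a critical
curve of constant R0,

    tau_I(beta) = c_ev / (8 beta),     R0_ev = 8(1 - exp(-c_ev/8)) ~ 4.5,

an emergent trade-off: transmission can only rise if virulence falls.  The
package implements the lattice dynamics (compiled with numba), host
mobility (Toffoli-Margolus block diffusion, annealed/quenched long-range
contacts), a metapopulation of patches exchanging hosts by state swaps, the
closed-form theory (R0, w_1D, mutant invasibility orderings, the critical
boundary), and the in-silico experiments: trade-off fitting, pairwise
invasion assays, diffusion bistability scans, lifetime scaling, and the
metapopulation rescue ratchet.  `docs/methods.md` has the full model
description and the measurement conventions.

## Worked example

Evaluate the theory:

```python
>>> from sirsevo import theory
>>> theory.exact_r0(1.0, 1.0)        # R0 at beta*tau_I = 1
5.056964470628461
>>> theory.w_one_d(1.0, 0.5, 1.0)    # 1D wave frequency
0.4
>>> theory.mutant_neighbourhood(theory.StrainTraits(1.2, 0.5), 0.01, 0.01).r0_ordering()
['++', '-+', '0', '+-', '--']
```

The first number says a strain with beta*tau_I = 1 infects ~5.06 of its 8
neighbours in a susceptible environment; the ordering says which one-step
mutants out-reproduce the focal strain in a well-mixed setting (beta up /
tau_I up first).

Run a small simulation from a config file:

```
$ cat demo.toml
L = 40
t_max = 30
init_beta = 1.2
init_tau_I = 0.5
seed = 4
$ sirsevo run demo.toml --out demo_out --pgm
terminated: t_max at t=30; outputs in demo_out
$ head -3 demo_out/trajectory.csv
time,mean_beta,mean_tau_I,frac_S,frac_I,frac_R,mean_R0,n_strains
0.0,1.1999999999999997,0.5,0.95,0.05,0.0,3.609506911247789,1
1.0,1.1999999999999997,0.5,0.060625,0.4125,0.526875,3.6095069112477884,1
```

The trajectory CSV tracks the infected-population mean traits, the S/I/R
fractions, the mean R0 (here 3.61, below the evolved value, so this
population sits in the disordered phase) and the number of distinct
strains; `demo_out/` also holds a lattice snapshot CSV, a PGM image of the
state field, and a JSON manifest sufficient to reproduce the run
bit-exactly.  Other subcommands: `invade1`, `invade2`, `lifetime`,
`scan-diffusion`, `metapop`, and `theory boundary` (CSV of the critical
curve, exact vs first-order).

Evolutionary convergence onto the trade-off takes ~10^5-10^6 sweeps; the
equivalent library calls are

```python
from sirsevo import SimConfig, Simulation, StrainTraits, experiments
sim = Simulation(SimConfig(L=100, init_strain=StrainTraits(1.0, 0.4), seed=101))
traj, term = sim.run(6000.0, sample_every=2.0)
fit = experiments.fit_tradeoff(traj, t_start=4000.0)
print(fit.c_hat, fit.r0_ev)   # ~6.7, ~4.5 at this scale
```

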