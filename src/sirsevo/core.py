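"""Stochastic synchronous-update lattice dynamics of the delayed SIRS model.

Hosts sit on a periodic L x L lattice with Moore neighbourhood (8 contacts).
Each site is susceptible (S), infected (I) or recovered (R); an infected site
carries a pathogen strain s = (beta, tau_I) with no built-in trade-off
between the transmission rate beta and the infection period tau_I.  Residence
times in I and R are deterministic (delta-distributed): a site leaves I when
its internal timer reaches tau_I and leaves R when it reaches tau_R, cycling
S -> I -> R -> S.  While infected, the strain mutates at rate mu, each trait
stepping independently by +/- a fixed increment.

The update is a fixed-time-step synchronous sweep: a susceptible site with
infected Moore neighbours Omega_j becomes infected with probability
``p = 1 - exp(-dt * sum(beta_n for n in Omega_j))`` and copies the strain of
one neighbour chosen proportionally to its transmission rate.  An infected
site cannot be re-infected by a second strain (superinfection exclusion).

The hot loop lives in :mod:`sirsevo._kernels` (numba); this module provides
the domain types, slow-but-transparent reference implementations of each
elementary rule, and the :class:`Simulation` driver.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import I_STATE, R_STATE, S_STATE

__all__ = [
    "S_STATE", "I_STATE", "R_STATE", "STATE_CHARS",
    "StrainTraits", "SimConfig", "LatticeState", "NeighbourhoodView",
    "Trajectory", "initialize", "infection_probability", "select_source",
    "mutate", "step", "Simulation", "run", "moore_neighbours",
]

STATE_CHARS = {S_STATE: "S", I_STATE: "I", R_STATE: "R"}
CHAR_STATES = {v: k for k, v in STATE_CHARS.items()}


@dataclass(frozen=True)
class StrainTraits:
    """An evolvable pathogen phenotype: transmission rate and infection period."""

    beta: float
    tau_I: float

    def __post_init__(self):
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")
        if not (np.isfinite(self.tau_I) and self.tau_I > 0):
            raise ValueError(f"tau_I must be finite and > 0, got {self.tau_I}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a single-lattice run.

    Defaults follow the standard parameterisation of the model: the recovery
    period tau_R = 1 sets the unit of time, dt = 0.01, mutation rate
    mu = 0.01 with trait increments d_beta = d_tau = 0.01, and runs start
    from 5% infected sites sharing one initial strain.
    """

    L: int = 100
    dt: float = 0.01
    tau_R: float = 1.0
    mu: float = 0.01
    d_beta: float = 0.01
    d_tau: float = 0.01
    init_infected_fraction: float = 0.05
    init_strain: StrainTraits = field(default_factory=lambda: StrainTraits(1.0, 0.5))
    seed: int = 0
    exact_source: bool = False  # exact exponential source weights instead of linearized
    per_trait_mutation: bool = False  # each trait mutates independently w.p. mu*dt

    def validate(self) -> None:
        errors = []
        if self.L < 1:
            errors.append(f"L must be >= 1, got {self.L}")
        if not self.dt > 0:
            errors.append(f"dt must be > 0, got {self.dt}")
        if not self.tau_R > 0:
            errors.append(f"tau_R must be > 0, got {self.tau_R}")
        if self.mu < 0:
            errors.append(f"mu must be >= 0, got {self.mu}")
        if self.mu * self.dt > 1:
            errors.append(f"mu*dt must be <= 1, got {self.mu * self.dt}")
        if self.d_beta < 0:
            errors.append(f"d_beta must be >= 0, got {self.d_beta}")
        if self.d_tau < 0:
            errors.append(f"d_tau must be >= 0, got {self.d_tau}")
        if not (0 < self.init_infected_fraction <= 1):
            errors.append("init_infected_fraction must be in (0, 1], got "
                          f"{self.init_infected_fraction}")
        elif round(self.init_infected_fraction * self.L ** 2) < 1:
            errors.append("init_infected_fraction * L^2 < 1: no epidemic can start")
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class LatticeState:
    """The full lattice: per-site state, timer and strain payload, plus clock.

    ``timer`` holds integer sweep counts; elapsed time since the last state
    change is ``timer * dt``.  ``beta``/``tau`` are meaningful only where
    ``state == I_STATE`` and are zero elsewhere.
    """

    state: np.ndarray  # int8 (nr, nc)
    timer: np.ndarray  # int64 sweep counts
    beta: np.ndarray   # float64
    tau: np.ndarray    # float64
    time: float = 0.0

    @property
    def shape(self):
        return self.state.shape

    @property
    def n_sites(self) -> int:
        return self.state.size

    @property
    def n_infected(self) -> int:
        return int(np.count_nonzero(self.state == I_STATE))

    def counts(self) -> dict:
        return {c: int(np.count_nonzero(self.state == s))
                for s, c in STATE_CHARS.items()}

    def copy(self) -> "LatticeState":
        return LatticeState(self.state.copy(), self.timer.copy(),
                            self.beta.copy(), self.tau.copy(), self.time)

    def infected_traits(self):
        """(beta, tau_I) arrays over currently infected sites."""
        mask = self.state == I_STATE
        return self.beta[mask], self.tau[mask]


@dataclass(frozen=True)
class NeighbourhoodView:
    """The infected Moore neighbours Omega_j of one susceptible site.

    Holds the transmission rates beta_n of the infected neighbours and
    derives the total infection probability p, the per-neighbour
    probabilities p_m and the normalized source-selection weights q_m.
    """

    betas: tuple

    def __post_init__(self):
        if any(b < 0 for b in self.betas):
            raise ValueError("negative transmission rate in neighbourhood")

    def p(self, dt: float) -> float:
        return infection_probability(self, dt)

    def p_m(self, dt: float) -> np.ndarray:
        return 1.0 - np.exp(-dt * np.asarray(self.betas, dtype=float))

    def q_m(self, dt: float, linearized: bool = True) -> np.ndarray:
        if not self.betas:
            raise ValueError("q_m undefined for an empty neighbourhood")
        if linearized:
            w = np.asarray(self.betas, dtype=float)
        else:
            w = self.p_m(dt)
        return w / w.sum()


def infection_probability(view: NeighbourhoodView, dt: float) -> float:
    """p = 1 - exp(-dt * sum of neighbour transmission rates); 0 if empty."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    betas = np.asarray(view.betas, dtype=float)
    if betas.size and (betas < 0).any():
        raise ValueError("negative transmission rate in neighbourhood")
    if betas.size == 0:
        return 0.0
    return float(1.0 - np.exp(-dt * betas.sum()))


def select_source(view: NeighbourhoodView, rng: np.random.Generator,
                  dt: float = 0.01, linearized: bool = True) -> int:
    """Pick the infecting neighbour with probability q_m.

    By default uses the small-dt linearization q_m = beta_m / sum(beta_n);
    with ``linearized=False`` the exact exponential weights
    p_m = 1 - exp(-dt*beta_m) are used instead.
    """
    if not view.betas:
        raise ValueError("cannot select a source from an empty neighbourhood")
    q = view.q_m(dt, linearized=linearized)
    return int(rng.choice(len(q), p=q))


def mutate(strain: StrainTraits, config: SimConfig,
           rng: np.random.Generator) -> StrainTraits:
    """With probability mu*dt step each trait by +/- its increment.

    Default semantics: one Bernoulli(mu*dt) event changes both traits, each
    sign drawn independently (the four (+,-) branches equally likely).  With
    ``config.per_trait_mutation`` each trait instead mutates in its own
    independent Bernoulli(mu*dt) trial.  Either way, a step that would make
    a trait non-positive leaves that trait unchanged, so rates stay strictly
    positive.
    """
    if config.per_trait_mutation:
        beta, tau = strain.beta, strain.tau_I
        if rng.random() < config.mu * config.dt:
            beta += config.d_beta if rng.random() < 0.5 else -config.d_beta
        if rng.random() < config.mu * config.dt:
            tau += config.d_tau if rng.random() < 0.5 else -config.d_tau
    else:
        if rng.random() >= config.mu * config.dt:
            return strain
        beta = strain.beta + (config.d_beta if rng.random() < 0.5 else -config.d_beta)
        tau = strain.tau_I + (config.d_tau if rng.random() < 0.5 else -config.d_tau)
    if beta <= 0:
        beta = strain.beta
    if tau <= 0:
        tau = strain.tau_I
    return StrainTraits(beta, tau)


def moore_neighbours(shape) -> tuple:
    """Index maps (nr, nc, 8) of the periodic Moore neighbourhood."""
    nr, nc = shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]
    nbr_r = np.empty((nr, nc, 8), dtype=np.int64)
    nbr_c = np.empty((nr, nc, 8), dtype=np.int64)
    for k, (di, dj) in enumerate(offs):
        nbr_r[:, :, k] = (ii + di) % nr
        nbr_c[:, :, k] = (jj + dj) % nc
    return nbr_r, nbr_c


def _empty_lattice(shape) -> LatticeState:
    return LatticeState(
        state=np.zeros(shape, dtype=np.int8),
        timer=np.zeros(shape, dtype=np.int64),
        beta=np.zeros(shape, dtype=np.float64),
        tau=np.zeros(shape, dtype=np.float64),
        time=0.0,
    )


def initialize(config: SimConfig, shape=None,
               rng: Optional[np.random.Generator] = None) -> LatticeState:
    """Seed a fresh lattice with round(fraction * N) infected sites.

    Infected sites are placed uniformly at random, all carrying the initial
    strain; every timer starts at zero and the clock at t = 0.
    """
    config.validate()
    if shape is None:
        shape = (config.L, config.L)
    n = shape[0] * shape[1]
    n_inf = int(round(config.init_infected_fraction * n))
    if n_inf < 1:
        raise ValueError("init_infected_fraction * N < 1: no epidemic can start")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    lattice = _empty_lattice(shape)
    idx = rng.choice(n, size=n_inf, replace=False)
    flat_state = lattice.state.reshape(-1)
    flat_beta = lattice.beta.reshape(-1)
    flat_tau = lattice.tau.reshape(-1)
    flat_state[idx] = I_STATE
    flat_beta[idx] = config.init_strain.beta
    flat_tau[idx] = config.init_strain.tau_I
    return lattice


@dataclass
class Trajectory:
    """Sampled time series of population-mean traits and compartment fractions.

    Strain summaries (mean_beta, mean_tau_I, mean_R0) are means over the
    currently infected sites; mean_R0 applies R0 = 8(1 - exp(-beta*tau_I))
    per site before averaging.  Rows with no infected sites carry NaN traits.
    """

    rows: list = field(default_factory=list)

    COLUMNS = ["time", "mean_beta", "mean_tau_I", "frac_S", "frac_I",
               "frac_R", "mean_R0", "n_strains"]

    def record(self, lattice: LatticeState) -> None:
        n = lattice.n_sites
        state = lattice.state
        n_i = int(np.count_nonzero(state == I_STATE))
        n_s = int(np.count_nonzero(state == S_STATE))
        n_r = n - n_i - n_s
        if n_i:
            b, t = lattice.infected_traits()
            mb = float(b.mean())
            mt = float(t.mean())
            mr0 = float(np.mean(8.0 * (1.0 - np.exp(-b * t))))
            ns = np.unique(np.stack([np.round(b, 9), np.round(t, 9)], axis=1),
                           axis=0).shape[0]
        else:
            mb = mt = mr0 = float("nan")
            ns = 0
        self.rows.append((lattice.time, mb, mt, n_s / n, n_i / n, n_r / n,
                          mr0, ns))

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class Simulation:
    """Driver for one lattice: buffers, RNG seeding, mixing schedule, sampling.

    All stochastic decisions of the sweep itself (infection draws, source
    selection, mutation, block rotations, long-range targets) come from the
    kernel's global RNG, which is seeded from ``config.seed`` at
    construction, so identical config + seed reproduce the full history
    bit-exactly.
    """

    def __init__(self, config: SimConfig, mobility=None, shape=None,
                 state: Optional[LatticeState] = None,
                 neighbours: Optional[tuple] = None):
        config.validate()
        self.config = config
        self.mobility = mobility
        if shape is None:
            shape = state.shape if state is not None else (config.L, config.L)
        self.shape = shape
        if mobility is not None:
            mobility.validate(shape=shape)
        ss = np.random.SeedSequence([int(config.seed), 0])
        self.rng = np.random.default_rng(ss)  # python-level draws (init placement)
        kernel_seed = int(np.random.SeedSequence([int(config.seed), 1]).generate_state(1)[0])
        _kernels.seed_rng(kernel_seed)
        if neighbours is not None:
            self.nbr_r, self.nbr_c = neighbours
        else:
            self.nbr_r, self.nbr_c = moore_neighbours(shape)
            if mobility is not None and mobility.quenched and mobility.p_long > 0:
                from .mobility import rewire_quenched
                self.nbr_r, self.nbr_c = rewire_quenched(
                    self.nbr_r, self.nbr_c, mobility.p_long, self.rng)
        self.lattice = state.copy() if state is not None else initialize(
            config, shape=shape, rng=self.rng)
        self._buf = _empty_lattice(shape)
        self._t0 = self.lattice.time
        self.step_count = 0
        self.n_mixes = 0
        self._p_long_annealed = (mobility.p_long
                                 if mobility is not None and not mobility.quenched
                                 else 0.0)
        self._mix_period = (mobility.gamma_period(config.dt)
                            if mobility is not None and mobility.D > 0 else 0)
        self.recording = False
        self._alloc_recorders()

    def _alloc_recorders(self):
        self.last_inf = np.full(self.shape, -1.0)
        self.int_sum = np.zeros(self.shape)
        self.int_sum2 = np.zeros(self.shape)
        self.int_cnt = np.zeros(self.shape, dtype=np.int64)

    def enable_infection_recording(self, reset: bool = True) -> None:
        """Start logging per-site inter-infection intervals from now on."""
        if reset:
            self._alloc_recorders()
        self.recording = True

    def set_neighbours(self, nbr_r, nbr_c) -> None:
        self.nbr_r, self.nbr_c = nbr_r, nbr_c

    def sweep(self) -> int:
        """One synchronous update (plus mixing when the schedule fires)."""
        cfg = self.config
        lat, buf = self.lattice, self._buf
        n_inf = _kernels.sweep(
            lat.state, lat.timer, lat.beta, lat.tau,
            buf.state, buf.timer, buf.beta, buf.tau,
            self.nbr_r, self.nbr_c,
            cfg.dt, cfg.tau_R, cfg.mu, cfg.d_beta, cfg.d_tau,
            cfg.per_trait_mutation, self._p_long_annealed, cfg.exact_source,
            self.recording, lat.time + cfg.dt,
            self.last_inf, self.int_sum, self.int_sum2, self.int_cnt)
        self.step_count += 1
        buf.time = self._t0 + self.step_count * cfg.dt  # exact, no fp drift
        self.lattice, self._buf = buf, lat
        if self._mix_period and self.step_count % self._mix_period == 0:
            _kernels.margolus(self.lattice.state, self.lattice.timer,
                              self.lattice.beta, self.lattice.tau,
                              self.n_mixes % 2)
            self.n_mixes += 1
        return n_inf

    def run(self, t_max: float, sample_every: float = 1.0,
            trajectory: Optional[Trajectory] = None,
            stop_on_extinction: bool = True,
            callback: Optional[Callable] = None):
        """Advance until ``time >= t_max`` or pathogen extinction.

        Returns (trajectory, termination) with termination in
        {"t_max", "extinction"}.  Samples are recorded every
        ``sample_every`` time units, including the initial state.
        """
        if t_max < 0:
            raise ValueError("t_max must be >= 0")
        cfg = self.config
        traj = trajectory if trajectory is not None else Trajectory()
        sample_steps = max(1, int(round(sample_every / cfg.dt)))
        n_steps = int(round((t_max - self.lattice.time) / cfg.dt))
        if not traj.rows:
            traj.record(self.lattice)
        termination = "t_max"
        for _ in range(max(0, n_steps)):
            n_inf = self.sweep()
            if self.step_count % sample_steps == 0:
                traj.record(self.lattice)
            if callback is not None:
                callback(self)
            if n_inf == 0 and stop_on_extinction:
                if self.step_count % sample_steps != 0:
                    traj.record(self.lattice)
                termination = "extinction"
                break
        return traj, termination


def step(lattice: LatticeState, config: SimConfig, mobility=None) -> LatticeState:
    """One synchronous sweep as a pure function (input lattice untouched).

    Randomness comes from the kernel's global stream; seed it first with
    ``sirsevo._kernels.seed_rng`` (or run inside a :class:`Simulation`,
    which seeds it from the config).
    """
    sim = Simulation.__new__(Simulation)
    sim.config = config
    sim.mobility = mobility
    sim.shape = lattice.shape
    sim.lattice = lattice.copy()
    sim._buf = _empty_lattice(lattice.shape)
    sim.nbr_r, sim.nbr_c = moore_neighbours(lattice.shape)
    sim._t0 = lattice.time
    sim.step_count = 0
    sim.n_mixes = 0
    sim._p_long_annealed = (mobility.p_long
                            if mobility is not None and not mobility.quenched
                            else 0.0)
    sim._mix_period = (mobility.gamma_period(config.dt)
                       if mobility is not None and mobility.D > 0 else 0)
    sim.recording = False
    sim._alloc_recorders()
    sim.sweep()
    return sim.lattice


def run(config: SimConfig, t_max: float, mobility=None, sample_every: float = 1.0,
        record_infections: bool = False, warmup: float = 0.0):
    """Convenience wrapper: build a Simulation, run it, return results.

    Returns (final LatticeState, Trajectory, termination).  When
    ``record_infections`` is set, per-site inter-infection intervals are
    accumulated after ``warmup`` time units (accessible on the returned
    simulation via :func:`run_sim`).
    """
    sim = Simulation(config, mobility=mobility)
    traj = Trajectory()
    if record_infections and warmup > 0:
        sim.run(min(warmup, t_max), sample_every=sample_every, trajectory=traj)
        sim.enable_infection_recording()
        if sim.lattice.time < t_max and sim.lattice.n_infected > 0:
            sim.run(t_max, sample_every=sample_every, trajectory=traj)
        term = "extinction" if sim.lattice.n_infected == 0 else "t_max"
        return sim.lattice, traj, term
    if record_infections:
        sim.enable_infection_recording()
    traj, term = sim.run(t_max, sample_every=sample_every, trajectory=traj)
    return sim.lattice, traj, term
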