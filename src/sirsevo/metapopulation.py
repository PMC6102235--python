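"""Metapopulation: a network of lattices exchanging hosts by state swaps.

After each synchronous sweep of all patches, every site jumps independently
with probability lambda * dt / N (N = sites per patch, lambda the per-host
jump rate, 0.01 by default).  A jumping site picks a uniformly random site
in a uniformly random adjacent patch and the two full site payloads (state,
timer, strain) are exchanged, so swaps conserve the global payload multiset;
all epidemiological change happens inside patches.

This exchange underlies the rescue/ratchet dynamic: disordered (mean-field)
patches collapse to the all-susceptible state in finite time and are later
re-seeded by jumps from surviving patches; patches seeded from an ordered
neighbour converge to the ordered phase themselves, so the global state is
driven toward full spatial order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import SimConfig, Simulation, Trajectory
from .mobility import MobilityParams

__all__ = ["MetapopConfig", "MetapopState", "MetapopSimulation", "jump_step",
           "run_metapop"]


def _resolve_adjacency(n_patches: int, adjacency) -> List[np.ndarray]:
    """Neighbour lists from 'complete' or an explicit symmetric edge list."""
    if isinstance(adjacency, str):
        if adjacency != "complete":
            raise ValueError(f"unknown adjacency spec {adjacency!r}")
        return [np.array([j for j in range(n_patches) if j != i], dtype=np.int64)
                for i in range(n_patches)]
    nbrs = [set() for _ in range(n_patches)]
    for a, b in adjacency:
        if a == b:
            raise ValueError(f"self-loop ({a}, {b}) in patch adjacency")
        if not (0 <= a < n_patches and 0 <= b < n_patches):
            raise ValueError(f"edge ({a}, {b}) out of range for {n_patches} patches")
        nbrs[a].add(b)
        nbrs[b].add(a)
    return [np.array(sorted(s), dtype=np.int64) for s in nbrs]


@dataclass(frozen=True)
class MetapopConfig:
    """Patch count, topology and jump rate of the metapopulation."""

    n_patches: int
    adjacency: object = "complete"  # 'complete' or list of (a, b) edges
    lambda_jump: float = 0.01

    def __post_init__(self):
        if self.n_patches < 1:
            raise ValueError(f"n_patches must be >= 1, got {self.n_patches}")
        if self.lambda_jump < 0:
            raise ValueError(f"lambda_jump must be >= 0, got {self.lambda_jump}")
        _resolve_adjacency(self.n_patches, self.adjacency)


@dataclass
class MetapopState:
    """The collection of patch lattices sharing one clock."""

    patches: list
    time: float = 0.0


def jump_step(sims: Sequence[Simulation], neighbours: List[np.ndarray],
              lambda_jump: float, rng: np.random.Generator) -> int:
    """Execute the post-sweep host exchange; returns the number of swaps.

    Each site jumps with probability lambda*dt/N.  Trials are executed in
    random global order and a site takes part in at most one swap per sweep
    (later trials touching it are skipped).
    """
    if lambda_jump == 0 or len(sims) < 2:
        return 0
    dt = sims[0].config.dt
    trials = []
    for a, sim in enumerate(sims):
        if neighbours[a].size == 0:
            continue
        n = sim.lattice.n_sites
        p = lambda_jump * dt / n
        k = rng.binomial(n, p)
        for site in rng.integers(0, n, size=k):
            trials.append((a, int(site)))
    if not trials:
        return 0
    rng.shuffle(trials)
    used = set()
    n_swaps = 0
    for a, site in trials:
        if (a, site) in used:
            continue
        b = int(rng.choice(neighbours[a]))
        tgt = int(rng.integers(0, sims[b].lattice.n_sites))
        if (b, tgt) in used:
            continue
        la, lb = sims[a].lattice, sims[b].lattice
        for arr_a, arr_b in ((la.state, lb.state), (la.timer, lb.timer),
                             (la.beta, lb.beta), (la.tau, lb.tau)):
            fa, fb = arr_a.reshape(-1), arr_b.reshape(-1)
            fa[site], fb[tgt] = fb[tgt], fa[site]
        used.add((a, site))
        used.add((b, tgt))
        n_swaps += 1
    return n_swaps


class MetapopSimulation:
    """Drive several patch Simulations with host exchange between sweeps.

    Patches share dt and advance in lockstep: one synchronous sweep of every
    patch (each applying its own mixing schedule), then the jump step.
    Patch sweeps draw from the kernel's global RNG in fixed patch order and
    the jump step has its own Generator, so runs are reproducible from the
    master seed.
    """

    def __init__(self, patch_configs: Sequence[SimConfig],
                 metapop: MetapopConfig,
                 mobility: Optional[Sequence[MobilityParams]] = None,
                 seed: int = 0):
        if len(patch_configs) != metapop.n_patches:
            raise ValueError("need one SimConfig per patch")
        dts = {c.dt for c in patch_configs}
        if len(dts) != 1:
            raise ValueError("all patches must share dt")
        if mobility is None:
            mobility = [None] * metapop.n_patches
        self.metapop = metapop
        self.neighbours = _resolve_adjacency(metapop.n_patches, metapop.adjacency)
        n0 = patch_configs[0].L ** 2
        if metapop.lambda_jump * patch_configs[0].dt / n0 > 1:
            raise ValueError("lambda*dt/N must be <= 1")
        self.sims = []
        for k, (cfg, mob) in enumerate(zip(patch_configs, mobility)):
            patch_seed = int(np.random.SeedSequence([int(seed), 2, k]).generate_state(1)[0])
            self.sims.append(Simulation(cfg.replace(seed=patch_seed), mobility=mob))
        self.jump_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
        self.events: list = []  # (time, patch, event)
        self._alive = [s.lattice.n_infected > 0 for s in self.sims]

    @property
    def time(self) -> float:
        return self.sims[0].lattice.time

    @property
    def state(self) -> MetapopState:
        return MetapopState([s.lattice for s in self.sims], self.time)

    def sweep(self) -> List[int]:
        """One lockstep sweep of all patches plus the jump step."""
        counts = [sim.sweep() for sim in self.sims]
        jump_step(self.sims, self.neighbours, self.metapop.lambda_jump,
                  self.jump_rng)
        # swaps can move infected hosts, so recount for event detection
        counts = [s.lattice.n_infected for s in self.sims]
        t = self.time
        for k, n in enumerate(counts):
            if self._alive[k] and n == 0:
                self.events.append((t, k, "extinction"))
                self._alive[k] = False
            elif not self._alive[k] and n > 0:
                self.events.append((t, k, "reinfection"))
                self._alive[k] = True
        return counts

    def run(self, t_max: float, sample_every: float = 1.0,
            stop_on_global_extinction: bool = True):
        """Advance to t_max; returns (per-patch Trajectories, events frame).

        Stops early only if the pathogen is extinct in every patch (no
        reservoir left to rescue from).
        """
        dt = self.sims[0].config.dt
        sample_steps = max(1, int(round(sample_every / dt)))
        n_steps = int(round((t_max - self.time) / dt))
        trajs = [Trajectory() for _ in self.sims]
        for traj, sim in zip(trajs, self.sims):
            traj.record(sim.lattice)
        for k in range(max(0, n_steps)):
            counts = self.sweep()
            if (k + 1) % sample_steps == 0:
                for traj, sim in zip(trajs, self.sims):
                    traj.record(sim.lattice)
            if stop_on_global_extinction and not any(counts):
                break
        return trajs, self.events_frame()

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time", "patch", "event"])


def run_metapop(patch_configs: Sequence[SimConfig], metapop: MetapopConfig,
                t_max: float, mobility=None, seed: int = 0,
                sample_every: float = 1.0):
    """Full metapopulation run: per-patch trajectories, event log, summary.

    The global summary aggregates, per sample time, the number of patches
    with surviving pathogen and the mean R0 over all infected sites.
    """
    msim = MetapopSimulation(patch_configs, metapop, mobility=mobility, seed=seed)
    trajs, events = msim.run(t_max, sample_every=sample_every)
    frames = [t.frame for t in trajs]
    times = frames[0]["time"]
    alive = np.zeros(len(times), dtype=int)
    r0_sum = np.zeros(len(times))
    r0_n = np.zeros(len(times), dtype=int)
    for f in frames:
        inf = f["frac_I"].to_numpy() > 0
        alive += inf
        good = inf & np.isfinite(f["mean_R0"].to_numpy())
        r0_sum[good] += f["mean_R0"].to_numpy()[good]
        r0_n[good] += 1
    with np.errstate(invalid="ignore"):
        summary = pd.DataFrame({
            "time": times,
            "n_patches_infected": alive,
            "mean_R0_infected_patches": np.where(r0_n > 0, r0_sum / np.maximum(r0_n, 1),
                                                 np.nan),
        })
    return msim, trajs, events, summary
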