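"""Configuration files, snapshots, run manifests and synthetic fixtures.

File formats
------------
* Config: one flat TOML file mirroring the SimConfig / MobilityParams /
  MetapopConfig fields (see KEYS below).  Unknown keys are an error.
* Trajectory: CSV with header
  ``time,mean_beta,mean_tau_I,frac_S,frac_I,frac_R,mean_R0,n_strains``.
* Snapshot: CSV of ``x,y,state,timer,beta,tau_I`` (0-based row-major
  coordinates, trait columns empty for non-infected sites), plus optional
  PGM image export of the state field.
* Manifest: JSON with the resolved config, seeds, package version, wall
  times and termination reason — sufficient to reproduce a run bit-exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
import tomllib
from dataclasses import dataclass

from typing import Optional

import numpy as np
import pandas as pd

from .core import (CHAR_STATES, I_STATE, STATE_CHARS, LatticeState, SimConfig,
                   StrainTraits)
from .metapopulation import MetapopConfig
from .mobility import MobilityParams

__all__ = ["ResolvedConfig", "load_config", "write_snapshot", "read_snapshot",
           "write_pgm", "RunManifest", "FixtureSpec", "generate_fixture"]

SIM_KEYS = {"L", "dt", "tau_R", "mu", "d_beta", "d_tau",
            "init_infected_fraction", "init_beta", "init_tau_I", "seed",
            "exact_source"}
MOBILITY_KEYS = {"diffusion_D", "p_long", "long_range_mode"}
METAPOP_KEYS = {"n_patches", "adjacency", "lambda_jump"}
RUN_KEYS = {"t_max", "sample_every"}
KEYS = SIM_KEYS | MOBILITY_KEYS | METAPOP_KEYS | RUN_KEYS


@dataclass(frozen=True)
class ResolvedConfig:
    sim: SimConfig
    mobility: MobilityParams
    metapop: Optional[MetapopConfig]
    t_max: float = 1000.0
    sample_every: float = 1.0


def load_config(path) -> ResolvedConfig:
    """Parse a flat TOML config, apply defaults, and validate everything.

    Every violated invariant is reported (not just the first); unknown keys
    are rejected so typos cannot silently fall back to defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    errors = []
    strain_kw = {}
    if "init_beta" in raw:
        strain_kw["beta"] = raw.pop("init_beta")
    if "init_tau_I" in raw:
        strain_kw["tau_I"] = raw.pop("init_tau_I")
    sim_kw = {k: raw[k] for k in SIM_KEYS & set(raw)}
    try:
        init_strain = StrainTraits(beta=strain_kw.get("beta", 1.0),
                                   tau_I=strain_kw.get("tau_I", 0.5))
        sim = SimConfig(init_strain=init_strain, **sim_kw)
        sim.validate()
    except ValueError as e:
        errors.append(str(e))
        sim = None
    try:
        mobility = MobilityParams(D=raw.get("diffusion_D", 0.0),
                                  p_long=raw.get("p_long", 0.0),
                                  long_range_mode=raw.get("long_range_mode",
                                                          "annealed"))
        if sim is not None:
            mobility.validate(shape=(sim.L, sim.L))
    except ValueError as e:
        errors.append(str(e))
        mobility = None
    metapop = None
    if METAPOP_KEYS & set(raw):
        try:
            adjacency = raw.get("adjacency", "complete")
            if isinstance(adjacency, list):
                adjacency = [tuple(e) for e in adjacency]
            metapop = MetapopConfig(n_patches=raw.get("n_patches", 1),
                                    adjacency=adjacency,
                                    lambda_jump=raw.get("lambda_jump", 0.01))
        except ValueError as e:
            errors.append(str(e))
    t_max = raw.get("t_max", 1000.0)
    sample_every = raw.get("sample_every", 1.0)
    if not t_max >= 0:
        errors.append(f"t_max must be >= 0, got {t_max}")
    if not sample_every > 0:
        errors.append(f"sample_every must be > 0, got {sample_every}")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return ResolvedConfig(sim=sim, mobility=mobility, metapop=metapop,
                          t_max=float(t_max), sample_every=float(sample_every))


# ---------------------------------------------------------------------------
# snapshots

def write_snapshot(lattice: LatticeState, path, dt: float) -> None:
    """Write the lattice as CSV rows x,y,state,timer,beta,tau_I.

    ``timer`` is written in time units (timer counts * dt); trait columns
    are left empty for sites that are not infected.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "state", "timer", "beta", "tau_I"])
        nr, nc = lattice.shape
        for i in range(nr):
            for j in range(nc):
                st = int(lattice.state[i, j])
                if st == I_STATE:
                    b = repr(float(lattice.beta[i, j]))
                    t = repr(float(lattice.tau[i, j]))
                else:
                    b = t = ""
                w.writerow([i, j, STATE_CHARS[st],
                            repr(int(lattice.timer[i, j]) * dt), b, t])


def read_snapshot(path, dt: float) -> LatticeState:
    """Read a snapshot CSV back into a LatticeState (inverse of write)."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["x", "y", "state", "timer", "beta", "tau_I"]:
            raise ValueError(f"{path}: line 1: bad snapshot header {header}")
        for ln, row in enumerate(reader, start=2):
            if len(row) != 6:
                raise ValueError(f"{path}: line {ln}: expected 6 fields, "
                                 f"got {len(row)}")
            try:
                x, y = int(row[0]), int(row[1])
                st = CHAR_STATES[row[2]]
                timer = int(round(float(row[3]) / dt))
                beta = float(row[4]) if row[4] else 0.0
                tau = float(row[5]) if row[5] else 0.0
            except (ValueError, KeyError) as e:
                raise ValueError(f"{path}: line {ln}: {e}") from None
            rows.append((x, y, st, timer, beta, tau))
    nr = max(r[0] for r in rows) + 1
    nc = max(r[1] for r in rows) + 1
    if len(rows) != nr * nc:
        raise ValueError(f"{path}: {len(rows)} rows do not fill a "
                         f"{nr}x{nc} lattice")
    lat = LatticeState(state=np.zeros((nr, nc), dtype=np.int8),
                       timer=np.zeros((nr, nc), dtype=np.int64),
                       beta=np.zeros((nr, nc)), tau=np.zeros((nr, nc)))
    for x, y, st, timer, beta, tau in rows:
        lat.state[x, y] = st
        lat.timer[x, y] = timer
        lat.beta[x, y] = beta
        lat.tau[x, y] = tau
    return lat


_PGM_GREY = {0: 255, 1: 0, 2: 128}  # S light, I black, R mid-grey


def write_pgm(lattice: LatticeState, path) -> None:
    """Export the state field as a plain-text (P2) PGM image."""
    nr, nc = lattice.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{nc} {nr}\n255\n")
        for i in range(nr):
            fh.write(" ".join(str(_PGM_GREY[int(s)])
                              for s in lattice.state[i]) + "\n")


# ---------------------------------------------------------------------------
# manifests

@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    termination: str = ""  # t_max | extinction | censored

    @classmethod
    def start(cls, config, seed: int) -> "RunManifest":
        from . import __version__
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
        return cls(config=config, seed=int(seed), version=__version__,
                   started=datetime.datetime.now().isoformat())

    def finish(self, termination: str) -> "RunManifest":
        self.finished = datetime.datetime.now().isoformat()
        self.termination = termination
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# synthetic fixtures

@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic dataset with known generating truth."""

    generator: str  # tradeoff_curve | lifetime_powerlaw | frozen_lattice
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0


def generate_fixture(spec: FixtureSpec):
    """Emit synthetic data plus the generating truth, for fit-recovery tests.

    Generators:

    * ``tradeoff_curve`` — (beta, tau_I) samples on tau_I = c/(8 beta) with
      optional Gaussian noise of s.d. ``sigma`` on tau_I.
      params: c (default 6.623), n (500), beta_range ((0.8, 3.0)), sigma (0).
    * ``lifetime_powerlaw`` — mean-lifetime table T(N) = a*N^b + T0 with
      optional relative Gaussian noise.
      params: a (5.3e-5), b (2.6), T0 (1.5e4), sizes (L in 40..150),
      rel_sigma (0).
    * ``frozen_lattice`` — a random lattice with given S/I/R fractions and a
      single strain, for microdynamics tests.
      params: L (20), frac_I (0.2), frac_R (0.2), beta (1.0), tau_I (0.5).
    """
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    if spec.generator == "tradeoff_curve":
        c = p.get("c", 6.623)
        n = p.get("n", 500)
        lo, hi = p.get("beta_range", (0.8, 3.0))
        sigma = p.get("sigma", 0.0)
        beta = rng.uniform(lo, hi, size=n)
        tau = c / (8.0 * beta)
        if sigma > 0:
            tau = tau + rng.normal(0.0, sigma, size=n)
        data = pd.DataFrame({"beta": beta, "tau_I": tau})
        return data, {"c": c, "sigma": sigma}
    if spec.generator == "lifetime_powerlaw":
        a = p.get("a", 5.3e-5)
        b = p.get("b", 2.6)
        t0 = p.get("T0", 1.5e4)
        sizes = np.asarray(p.get("sizes", [40, 60, 80, 100, 120, 150]))
        rel_sigma = p.get("rel_sigma", 0.0)
        N = sizes.astype(float) ** 2
        T = a * N ** b + t0
        if rel_sigma > 0:
            T = T * (1.0 + rng.normal(0.0, rel_sigma, size=len(T)))
        data = pd.DataFrame({"L": sizes, "N": N.astype(int), "T": T})
        return data, {"a": a, "b": b, "T0": t0, "rel_sigma": rel_sigma}
    if spec.generator == "frozen_lattice":
        L = p.get("L", 20)
        frac_i = p.get("frac_I", 0.2)
        frac_r = p.get("frac_R", 0.2)
        strain = StrainTraits(p.get("beta", 1.0), p.get("tau_I", 0.5))
        states = rng.choice([0, 1, 2], size=(L, L),
                            p=[1 - frac_i - frac_r, frac_i, frac_r])
        lat = LatticeState(state=states.astype(np.int8),
                           timer=np.zeros((L, L), dtype=np.int64),
                           beta=np.where(states == 1, strain.beta, 0.0),
                           tau=np.where(states == 1, strain.tau_I, 0.0))
        return lat, {"strain": strain, "frac_I": frac_i, "frac_R": frac_r}
    raise ValueError(f"unknown fixture generator {spec.generator!r}")
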