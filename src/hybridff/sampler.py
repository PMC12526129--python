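"""Desk-scale equilibrium samplers for the hybrid energy model.

Two routes produce samples of small systems:

* a BAOAB Langevin integrator over full particle coordinates, optionally
  with a harmonic umbrella bias on the centre-of-mass (COM) separation of
  two particle groups;
* a Metropolis Monte-Carlo sampler over the scalar pair separation of a
  dimer, which is exact for an isolated pair and orders of magnitude
  cheaper — the workhorse for umbrella-window generation in tests.

Both are seed-deterministic: identical seed, identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import HybridPairTable, PairModel
from .system import ParticleSystem, minimum_image
from .units import kt


@dataclass
class SimulationConditions:
    """Thermostat settings for toy dynamics.

    Defaults follow the production protocol: 310 K.  Friction (1/ps),
    time step (ps) and step count are desk-scale choices.
    """

    temperature: float = 310.0
    friction: float = 2.0
    timestep: float = 0.01
    n_steps: int = 10000
    seed: int = 0
    sample_every: int = 10
    thermostat: str = "langevin"

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")
        if self.timestep <= 0:
            raise ValueError("time step must be positive")


@dataclass
class UmbrellaWindow:
    """One biased sampling window along a pair COM separation.

    ``samples`` is the full recorded series (nm); :attr:`production`
    drops the first ``discard`` entries (equilibration).
    """

    center: float
    force_constant: float
    samples: np.ndarray
    discard: int = 0
    seed: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if len(self.samples) <= self.discard:
            raise ValueError("window has no samples left after equilibration discard")
        if np.any(self.samples <= 0):
            raise ValueError("COM separations must be positive")

    @property
    def production(self) -> np.ndarray:
        return self.samples[self.discard:]

    def bias_energy(self, r) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(r) - self.center) ** 2


def generate_window_centers(r_min: float = 0.25, r_max: float = 1.0, n: int = 20) -> np.ndarray:
    """Uniformly spaced umbrella-window centers including both endpoints.

    Defaults reproduce the production window protocol: 20 windows
    spanning COM separations of 0.25-1.0 nm (2.5-10 angstrom).
    """
    if n < 2:
        raise ValueError("need at least 2 windows")
    if not (0 < r_min < r_max):
        raise ValueError("require r_max > r_min > 0")
    return np.linspace(r_min, r_max, n)


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass
class MDState:
    positions: np.ndarray
    velocities: np.ndarray

    def copy(self) -> "MDState":
        return MDState(self.positions.copy(), self.velocities.copy())


@dataclass
class ComBias:
    """Harmonic umbrella bias on the COM separation of two index groups."""

    group_a: np.ndarray
    group_b: np.ndarray
    center: float
    force_constant: float

    def __post_init__(self):
        self.group_a = np.asarray(self.group_a, dtype=int)
        self.group_b = np.asarray(self.group_b, dtype=int)
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            raise ValueError("bias groups must be non-empty")
        if np.intersect1d(self.group_a, self.group_b).size:
            raise ValueError("bias groups must be disjoint")

    def separation(self, positions, masses, box=None) -> float:
        ma = masses[self.group_a]
        mb = masses[self.group_b]
        com_a = (positions[self.group_a] * ma[:, None]).sum(0) / ma.sum()
        com_b = (positions[self.group_b] * mb[:, None]).sum(0) / mb.sum()
        d = minimum_image(com_a - com_b, box)
        return float(np.linalg.norm(d))

    def add_forces(self, positions, masses, forces, box=None) -> float:
        ma = masses[self.group_a]
        mb = masses[self.group_b]
        com_a = (positions[self.group_a] * ma[:, None]).sum(0) / ma.sum()
        com_b = (positions[self.group_b] * mb[:, None]).sum(0) / mb.sum()
        d = minimum_image(com_a - com_b, box)
        r = float(np.linalg.norm(d))
        fmag = -self.force_constant * (r - self.center)
        unit = d / r
        forces[self.group_a] += (ma / ma.sum())[:, None] * (fmag * unit)
        forces[self.group_b] -= (mb / mb.sum())[:, None] * (fmag * unit)
        return r


def langevin_step(state: MDState, force_fn, masses, conditions: SimulationConditions, rng, forces=None):
    """One BAOAB Langevin update; returns (new_state, new_forces).

    With friction -> 0 and temperature -> 0 the O step becomes the
    identity and the scheme reduces to velocity Verlet (symplectic,
    energy conserving).
    """
    dt = conditions.timestep
    m = masses[:, None]
    f = force_fn(state.positions) if forces is None else forces
    if not np.all(np.isfinite(f)):
        bad = int(np.flatnonzero(~np.isfinite(f).all(axis=1))[0])
        raise FloatingPointError(f"non-finite force on particle {bad}")
    v = state.velocities + 0.5 * dt * f / m
    x = state.positions + 0.5 * dt * v
    c1 = np.exp(-conditions.friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1) * kt(conditions.temperature))
    v = c1 * v + c2 / np.sqrt(m) * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    f_new = force_fn(x)
    v = v + 0.5 * dt * f_new / m
    return MDState(x, v), f_new


def run_langevin(
    system: ParticleSystem,
    table: HybridPairTable,
    conditions: SimulationConditions,
    bias: ComBias | None = None,
    initial_velocities=None,
    record=None,
):
    """Integrate a system with BAOAB Langevin dynamics.

    Returns ``(final_system, trace)`` where ``trace`` is a dict of
    recorded series: ``"r"`` (bias separation, when biased) and any extra
    callables passed via ``record`` (name -> f(positions)).  Sampling
    happens every ``conditions.sample_every`` steps.
    """
    model = PairModel(system, table)
    rng = np.random.default_rng(conditions.seed)
    masses = system.masses
    if initial_velocities is None:
        if conditions.temperature > 0:
            v0 = rng.standard_normal((len(system), 3)) * np.sqrt(kt(conditions.temperature) / masses[:, None])
        else:
            v0 = np.zeros((len(system), 3))
    else:
        v0 = np.asarray(initial_velocities, dtype=float)
    state = MDState(system.positions.copy(), v0)

    def force_fn(x):
        f = model.forces(x)
        if bias is not None:
            bias.add_forces(x, masses, f, system.box)
        return f

    forces = force_fn(state.positions)
    trace: dict[str, list] = {"r": []} if bias is not None else {}
    extra = record or {}
    for name in extra:
        trace[name] = []
    for step in range(conditions.n_steps):
        state, forces = langevin_step(state, force_fn, masses, conditions, rng, forces)
        if (step + 1) % conditions.sample_every == 0:
            if bias is not None:
                trace["r"].append(bias.separation(state.positions, masses, system.box))
            for name, fn in extra.items():
                trace[name].append(fn(state.positions))
    out = {k: np.asarray(v) for k, v in trace.items()}
    return system.with_positions(state.positions), out


# ---------------------------------------------------------------------------
# Metropolis sampling of a scalar pair separation
# ---------------------------------------------------------------------------

def sample_pair_distance_mc(
    potential,
    r0: float,
    force_constant: float,
    temperature: float = 310.0,
    n_samples: int = 4000,
    seed: int = 0,
    r_start: float | None = None,
    step: float | None = None,
    r_floor: float = 0.05,
    stride: int = 2,
):
    """Metropolis chain over a scalar separation r under U(r) + bias.

    Samples the 1-D Boltzmann density exp(-beta*(U(r) + k/2 (r-r0)^2))
    with Gaussian proposals (no Jacobian — r is treated as a 1-D
    coordinate, matching the default PMF convention).  Deterministic per
    seed.  Returns an array of ``n_samples`` values recorded every
    ``stride`` accepted-or-rejected moves.
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / kt(temperature)
    if step is None:
        # scale proposals to the bias stiffness so stiff windows still move
        step = float(np.clip(0.7 * np.sqrt(kt(temperature) / max(force_constant, 1.0)), 0.005, 0.05))

    def u_tot(r):
        return potential(r) + 0.5 * force_constant * (r - r0) ** 2

    r = float(r0 if r_start is None else r_start)
    if r <= r_floor:
        r = r_floor + step
    u = u_tot(r)
    out = np.empty(n_samples)
    n_moves = n_samples * stride
    proposals = rng.normal(0.0, step, size=n_moves)
    accept_u = rng.random(n_moves)
    k = 0
    for i in range(n_moves):
        r_new = r + proposals[i]
        if r_new > r_floor:
            u_new = u_tot(r_new)
            if u_new <= u or accept_u[i] < np.exp(-beta * (u_new - u)):
                r, u = r_new, u_new
        if (i + 1) % stride == 0:
            out[k] = r
            k += 1
    return out


def run_umbrella_window(
    system: ParticleSystem,
    table: HybridPairTable,
    selection_a,
    selection_b,
    center: float,
    force_constant: float = 1000.0,
    conditions: SimulationConditions | None = None,
    method: str = "langevin",
    discard_fraction: float = 0.1,
) -> UmbrellaWindow:
    """Sample one umbrella window of the COM separation of two groups.

    The default force constant is the production value, 1000 kJ/mol/nm^2.
    ``method="mc"`` runs the scalar Metropolis sampler over the effective
    pair potential (exact for an isolated dimer, one particle per group);
    ``method="langevin"`` runs biased dynamics on the full system.  The
    first ``discard_fraction`` of the series is marked as equilibration.
    """
    conditions = conditions or SimulationConditions()
    sel_a = np.asarray(selection_a, dtype=int)
    sel_b = np.asarray(selection_b, dtype=int)
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("selections must be disjoint")
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("selections must be non-empty")

    if method == "mc":
        if len(sel_a) != 1 or len(sel_b) != 1:
            raise ValueError("mc method requires single-particle selections")
        i, j = int(sel_a[0]), int(sel_b[0])
        from .forcefield import pair_potential

        pot = pair_potential(
            table, system.types[i], system.types[j], system.resolution[i], system.resolution[j]
        )
        n = max(1, conditions.n_steps // conditions.sample_every)
        series = sample_pair_distance_mc(
            pot, center, force_constant,
            temperature=conditions.temperature, n_samples=n, seed=conditions.seed,
        )
    elif method == "langevin":
        bias = ComBias(sel_a, sel_b, center, force_constant)
        _, trace = run_langevin(system, table, conditions, bias=bias)
        series = trace["r"]
    else:
        raise ValueError(f"unknown sampling method {method!r}")

    discard = int(discard_fraction * len(series))
    return UmbrellaWindow(center, force_constant, series, discard=discard, seed=conditions.seed)


def sample_umbrella_set(
    system: ParticleSystem,
    table: HybridPairTable,
    selection_a,
    selection_b,
    centers=None,
    force_constant: float = 1000.0,
    conditions: SimulationConditions | None = None,
    method: str = "mc",
) -> list[UmbrellaWindow]:
    """Run one window per center (seed offset by window index)."""
    conditions = conditions or SimulationConditions()
    centers = generate_window_centers() if centers is None else np.asarray(centers)
    windows = []
    for w, c in enumerate(centers):
        cond = SimulationConditions(
            temperature=conditions.temperature,
            friction=conditions.friction,
            timestep=conditions.timestep,
            n_steps=conditions.n_steps,
            seed=conditions.seed + w,
            sample_every=conditions.sample_every,
        )
        windows.append(
            run_umbrella_window(
                system, table, selection_a, selection_b, float(c),
                force_constant=force_constant, conditions=cond, method=method,
            )
        )
    return windows
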