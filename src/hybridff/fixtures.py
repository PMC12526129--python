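"""Deterministic generators for every test input.

All generators are pure functions of their arguments (bit-reproducible
per seed): side-chain-analog dimer boxes for the umbrella protocol, toy
homopolymers for scaling calibration, ideal beta-sheets of known
registry, a micelle-forming amphiphile mixture, and synthetic growth /
encounter series for the kinetics fitters.

The per-analog interaction parameters below are invented desk-scale
surrogates (synthetic, not a published force field): they order the
analogs plausibly by hydrophobicity and size so the toy pipeline has
chemistry-like variety, nothing more.
"""

from __future__ import annotations

import numpy as np

from .aggregation import GrowthSeries, StrandSegment
from .forcefield import HybridPairTable
from .system import ParticleSystem

#: The 12 representative side-chain analogs of the cross-interaction fit
#: (several MARTINI bead chemistries share a type, e.g. Leu/Ile, Val/Pro).
ANALOG_LABELS = (
    "LEU", "VAL", "CYS", "SER", "ASN", "GLN",
    "GLU", "ARG", "LYS", "HIS", "PHE", "TRP",
)

#: label -> (epsilon kJ/mol, sigma nm, charge e, mass amu); synthetic toy values.
ANALOG_PARAMS = {
    "LEU": (3.5, 0.47, 0.0, 57.0),
    "VAL": (3.2, 0.45, 0.0, 43.0),
    "CYS": (2.8, 0.43, 0.0, 47.0),
    "SER": (2.2, 0.40, 0.0, 31.0),
    "ASN": (2.4, 0.44, 0.0, 58.0),
    "GLN": (2.5, 0.46, 0.0, 72.0),
    "GLU": (2.3, 0.46, -1.0, 73.0),
    "ARG": (2.4, 0.50, 1.0, 100.0),
    "LYS": (2.3, 0.49, 1.0, 72.0),
    "HIS": (2.9, 0.48, 0.0, 81.0),
    "PHE": (3.8, 0.50, 0.0, 77.0),
    "TRP": (4.2, 0.54, 0.0, 116.0),
}

#: Analog dimer box (nm) matching the umbrella-protocol box.
DIMER_BOX = (3.0, 4.0, 3.0)

STRAND_RESIDUES = ("L1", "V2", "F3", "F4", "A5")
CA_SPACING = 0.35  # nm, intra-strand Calpha spacing at extended geometry
STRAND_SPACING = 0.48  # nm, inter-strand sheet spacing


def default_pair_table(eps_cg: float = 0.2, eps_dual: float = 0.8, **kwargs) -> HybridPairTable:
    """Pair table over the 12 analogs (self terms; cross pairs combine).

    The backbone "P5" coil bead is aliased to the Asn side-chain bead,
    which shares the same MARTINI type.
    """
    pairs = {(a, a): (ANALOG_PARAMS[a][0], ANALOG_PARAMS[a][1]) for a in ANALOG_LABELS}
    charges = {a: ANALOG_PARAMS[a][2] for a in ANALOG_LABELS}
    return HybridPairTable(
        pairs=pairs,
        charges=charges,
        eps_cg=eps_cg,
        eps_dual=eps_dual,
        aliases={"BB_P5": "ASN"},
        **kwargs,
    )


# ---------------------------------------------------------------------------
# analog dimers
# ---------------------------------------------------------------------------

def analog_dimer(
    label_ua: str,
    label_cg: str,
    separation: float = 0.6,
    box=DIMER_BOX,
) -> ParticleSystem:
    """One UA particle and one CG particle at a given separation (nm)."""
    for lab in (label_ua, label_cg):
        if lab not in ANALOG_PARAMS:
            raise ValueError(f"unknown analog label {lab!r}")
    p = ANALOG_PARAMS
    center = np.asarray(box) / 2.0
    positions = [center - [separation / 2, 0, 0], center + [separation / 2, 0, 0]]
    return ParticleSystem.create(
        positions,
        resolution=np.array(["UA", "CG"], dtype=object),
        types=np.array([label_ua, label_cg], dtype=object),
        charges=np.array([p[label_ua][2], p[label_cg][2]]),
        masses=np.array([p[label_ua][3], p[label_cg][3]]),
        chains=np.array([0, 1]),
        resnames=np.array([label_ua, label_cg], dtype=object),
        box=np.asarray(box, dtype=float),
    )


def enumerate_analog_pairs(analogs=ANALOG_LABELS, separation: float = 0.6):
    """One dimer system per ORDERED analog pair (12 analogs -> 144).

    Ordered because each heterodimer appears twice with the resolutions
    swapped: (A, B) puts A at the UA level and B at the CG level,
    (B, A) the reverse.  Returns a list of
    ``((label_ua, label_cg), ParticleSystem)``.
    """
    analogs = list(analogs)
    if len(analogs) == 0:
        raise ValueError("analog list must be non-empty")
    if len(set(analogs)) != len(analogs):
        raise ValueError("duplicate analog labels")
    return [
        ((a, b), analog_dimer(a, b, separation=separation))
        for a in analogs
        for b in analogs
    ]


# ---------------------------------------------------------------------------
# beta sheets and helices
# ---------------------------------------------------------------------------

def build_beta_sheet(
    n_strands: int = 2,
    registry: str = "parallel",
    register_shift: int = 0,
) -> ParticleSystem:
    """Ideal Calpha-trace beta-sheet with exact, known registry.

    Strands are fully extended (0.35 nm Calpha spacing) and stacked at
    0.48 nm; residues carry the L1 V2 F3 F4 A5 labels.  ``parallel``
    aligns all strands identically (L1 over L1); ``antiparallel``
    reverses every odd strand and offsets it so the in-register
    antiparallel pairing (L1-F4, V2-F3, F3-V2, F4-L1) holds exactly.
    ``register_shift`` slides every odd strand by that many residue
    spacings along the strand axis, producing off-register ("other")
    pairs.
    """
    if n_strands < 2:
        raise ValueError("need at least 2 strands")
    if registry not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown registry {registry!r}")
    n_res = len(STRAND_RESIDUES)
    if abs(register_shift) >= n_res:
        raise ValueError("register shift must be smaller than the strand length")
    positions, chains, resids, resnames = [], [], [], []
    for s in range(n_strands):
        reversed_strand = registry == "antiparallel" and s % 2 == 1
        shift = register_shift * CA_SPACING if s % 2 == 1 else 0.0
        for k in range(n_res):
            if reversed_strand:
                x = (n_res - 2 - k) * CA_SPACING  # F4 sits across L1
            else:
                x = k * CA_SPACING
            positions.append([x + shift, s * STRAND_SPACING, 0.0])
            chains.append(s)
            resids.append(k)
            resnames.append(STRAND_RESIDUES[k])
    return ParticleSystem.create(
        np.asarray(positions),
        resolution="UA",
        types="CA",
        charges=0.0,
        masses=110.0,
        chains=np.asarray(chains),
        resids=np.asarray(resids),
        resnames=np.asarray(resnames, dtype=object),
    )


def build_alpha_helix(n_residues: int = 8) -> ParticleSystem:
    """Ideal Calpha-trace alpha-helix (100 deg turn, 0.15 nm rise).

    The i-1 to i+1 Calpha distance on this geometry is ~0.55 nm, below
    the 0.64 nm pseudo-extension threshold, so no residue is extended.
    """
    k = np.arange(n_residues)
    theta = np.deg2rad(100.0) * k
    positions = np.column_stack([0.23 * np.cos(theta), 0.23 * np.sin(theta), 0.15 * k])
    return ParticleSystem.create(
        positions,
        resolution="UA",
        types="CA",
        masses=110.0,
        chains=0,
        resids=k,
        resnames=np.asarray(["A%d" % (i + 1) for i in k], dtype=object),
    )


def strand_segments_from_sheet(system: ParticleSystem) -> list[StrandSegment]:
    """StrandSegment per chain, built from construction metadata.

    Used for registry tests where the geometry is exact by construction
    and detection is not the property under test.
    """
    segments = []
    for c in np.unique(system.chains):
        idx = np.flatnonzero((system.chains == c) & (system.types == "CA"))
        order = np.argsort(system.resids[idx])
        idx = idx[order]
        segments.append(
            StrandSegment(
                chain=int(c),
                residues=tuple(int(r) for r in system.resids[idx]),
                ca_indices=idx,
                labels=tuple(str(x) for x in system.resnames[idx]),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# toy homopolymer
# ---------------------------------------------------------------------------

def build_homopolymer(
    n_beads: int = 10,
    epsilon: float = 4.0,
    sigma: float = 0.45,
    bond_length: float = 0.38,
    bond_k: float = 8000.0,
    resolution: str = "CG",
):
    """Straight bead chain plus its pair table (single bead type "PB")."""
    positions = np.zeros((n_beads, 3))
    positions[:, 0] = np.arange(n_beads) * bond_length
    bonds = np.column_stack([np.arange(n_beads - 1), np.arange(1, n_beads)])
    system = ParticleSystem.create(
        positions,
        resolution=resolution,
        types="PB",
        masses=72.0,
        chains=0,
        bonds=bonds,
        bond_r0=bond_length,
        bond_k=bond_k,
    )
    table = HybridPairTable(pairs={("PB", "PB"): (epsilon, sigma)}, eps_cg=1.0, eps_dual=1.0)
    return system, table


# ---------------------------------------------------------------------------
# micelle-forming amphiphile toy
# ---------------------------------------------------------------------------

def build_micelle_toy(
    n_amphiphiles: int = 16,
    head_charge: float = 1.0,
    tail_epsilon: float = 6.0,
    head_epsilon: float = 1.0,
    sigma: float = 0.47,
    box_length: float = 4.0,
    bond_k: float = 4000.0,
    seed: int = 0,
    max_retries: int = 2000,
):
    """Randomly placed two-bead amphiphiles: sticky UA tail, charged CG head.

    A desk-scale surrogate for the core-corona architecture: hydrophobic
    tails (strong LJ cohesion) drive clustering while charged heads
    (weak LJ, repulsive Coulomb) are pushed to the periphery.  With
    ``head_charge=0`` and ``head_epsilon == tail_epsilon`` the two bead
    species are symmetric and no radial ordering is expected (control).
    Initial placement is non-overlapping with bounded retries; identical
    seed gives an identical configuration.  Returns (system, table).
    """
    if n_amphiphiles < 2:
        raise ValueError("need at least 2 amphiphiles")
    rng = np.random.default_rng(seed)
    box = np.full(3, float(box_length))
    positions = []
    min_sep2 = 0.40**2
    for _ in range(n_amphiphiles):
        for attempt in range(max_retries):
            tail = rng.uniform(0, box_length, 3)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            head = tail + sigma * direction
            ok = True
            for p in positions:
                d = tail - p
                d -= box * np.round(d / box)
                d2h = head - p
                d2h -= box * np.round(d2h / box)
                if (d @ d) < min_sep2 or (d2h @ d2h) < min_sep2:
                    ok = False
                    break
            if ok:
                positions.extend([tail, head])
                break
        else:
            raise RuntimeError(
                f"could not place amphiphile without overlap after {max_retries} retries"
            )
    n = n_amphiphiles
    bonds = np.column_stack([2 * np.arange(n), 2 * np.arange(n) + 1])
    system = ParticleSystem.create(
        np.asarray(positions),
        resolution=np.asarray(["UA", "CG"] * n, dtype=object),
        types=np.asarray(["TL", "HD"] * n, dtype=object),
        charges=np.asarray([0.0, head_charge] * n),
        masses=72.0,
        chains=np.repeat(np.arange(n), 2),
        resids=np.tile([0, 1], n),
        resnames=np.asarray(["TL", "HD"] * n, dtype=object),
        box=box,
        bonds=bonds,
        bond_r0=sigma,
        bond_k=bond_k,
    )
    table = HybridPairTable(
        pairs={("TL", "TL"): (tail_epsilon, sigma), ("HD", "HD"): (head_epsilon, sigma)},
        charges={"HD": head_charge, "TL": 0.0},
        eps_cg=1.0,
        eps_dual=1.0,
    )
    return system, table


def micelle_ordering_run(
    seed: int,
    n_amphiphiles: int = 16,
    head_charge: float = 1.0,
    tail_epsilon: float = 6.0,
    head_epsilon: float = 1.0,
    n_steps: int = 15000,
    record_every: int = 500,
) -> float:
    """Relax a micelle toy and return its time-averaged ordering statistic.

    Runs Langevin dynamics at 310 K, records the head-minus-tail radial
    ordering of the largest cluster every ``record_every`` steps over the
    second half of the run, and averages — single frames are too noisy
    for the symmetry control.  Deterministic per seed.
    """
    from .aggregation import radial_ordering
    from .sampler import SimulationConditions, run_langevin

    system, table = build_micelle_toy(
        n_amphiphiles,
        head_charge=head_charge,
        tail_epsilon=tail_epsilon,
        head_epsilon=head_epsilon,
        seed=seed,
    )
    conditions = SimulationConditions(
        temperature=310.0, friction=2.0, timestep=0.02,
        n_steps=n_steps, seed=seed, sample_every=record_every,
    )
    stats: list[float] = []

    def probe(positions):
        frame = system.with_positions(positions)
        stats.append(radial_ordering(frame))
        return stats[-1]

    run_langevin(system, table, conditions, record={"ordering": probe})
    half = len(stats) // 2
    return float(np.mean(stats[half:]))


# ---------------------------------------------------------------------------
# synthetic series
# ---------------------------------------------------------------------------

def synth_growth_series(
    alpha: float,
    n_points: int = 50,
    noise_sd: float = 0.1,
    t_span=(1.0, 100.0),
    scale: float = 10.0,
    seed: int = 0,
) -> GrowthSeries:
    """Power-law growth series n(t) = scale * t^alpha * exp(eta).

    ``eta ~ Normal(0, noise_sd^2)`` i.i.d. per point (lognormal
    multiplicative noise, the natural noise model for a log-log fit).
    Deterministic per seed.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if n_points < 5:
        raise ValueError("need at least 5 points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.geomspace(t_span[0], t_span[1], n_points)
    eta = rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else np.zeros(n_points)
    n = scale * t**alpha * np.exp(eta)
    return GrowthSeries(times=t, sizes=n)


def synth_oscillating_distance_series(
    n_dips: int = 3,
    d_min: float = 25.0,
    d_max: float = 70.0,
    points_per_cycle: int = 40,
):
    """(times, distances) oscillating between d_min and d_max (angstrom).

    The series starts and ends at the midpoint, dipping below the
    low-distance region exactly ``n_dips`` times — a constructed
    encounter-without-fusion trace.
    """
    n = n_dips * points_per_cycle + 1
    t = np.arange(n, dtype=float)
    mid = 0.5 * (d_min + d_max)
    amp = 0.5 * (d_max - d_min)
    d = mid - amp * np.sin(2.0 * np.pi * n_dips * t / (n - 1))
    return t, d


def double_well_potential(barrier: float = 6.0, r_minima=(0.45, 0.75)):
    """Quartic double well with minima at r_minima and the given barrier.

    U(r) = barrier * ((r-m)^2 - w^2)^2 / w^4 with m the midpoint and w
    the half-separation; U is 0 at both minima and ``barrier`` at the
    top.  A standard analytic oracle for umbrella sampling + WHAM.
    """
    m = 0.5 * (r_minima[0] + r_minima[1])
    w = 0.5 * (r_minima[1] - r_minima[0])

    def u(r):
        r = np.asarray(r, dtype=float)
        out = barrier * ((r - m) ** 2 - w**2) ** 2 / w**4
        return out if out.ndim else float(out)

    return u
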