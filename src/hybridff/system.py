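"""Particle systems with mixed united-atom / coarse-grained resolution.

A :class:`ParticleSystem` is the in-memory container shared by the energy
model, the toy samplers, the fixtures and the analysis code.  Every particle
carries exactly one resolution tag (``"UA"`` or ``"CG"``); the tag decides
which of the three energy terms (UA-UA, CG-CG or cross-resolution) a pair
contributes to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

RESOLUTIONS = ("UA", "CG")


@dataclass
class ParticleSystem:
    """Coordinates plus per-particle metadata for a hybrid-resolution system.

    Parameters
    ----------
    positions : (N, 3) float array, nm.
    resolution : (N,) array of ``"UA"``/``"CG"`` tags.
    types : (N,) array of type labels resolving in a pair table.
    charges : (N,) float array, elementary charges.
    masses : (N,) float array, amu; must be positive.
    chains : (N,) int array, chain membership (0-based).
    resids : (N,) int array, residue index within the chain (0-based).
    resnames : (N,) array of residue labels (e.g. ``"L1"`` ... ``"A5"``).
    box : optional (3,) float array of orthorhombic box lengths, nm.
    exclusions : set of symmetric ``(i, j)`` index pairs excluded from
        nonbonded sums (both orders stored).
    bonds, bond_r0, bond_k : harmonic bond terms for toy systems
        ((M, 2) int indices, equilibrium lengths nm, force constants
        kJ mol^-1 nm^-2).
    """

    positions: np.ndarray
    resolution: np.ndarray
    types: np.ndarray
    charges: np.ndarray
    masses: np.ndarray
    chains: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    box: np.ndarray | None = None
    exclusions: frozenset = field(default_factory=frozenset)
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        n = len(self.positions)
        self.resolution = np.asarray(self.resolution, dtype=object)
        self.types = np.asarray(self.types, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.chains = np.asarray(self.chains, dtype=int)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        for name in ("resolution", "types", "charges", "masses", "chains", "resids", "resnames"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length {n}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        self.bond_k = np.asarray(self.bond_k, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        bad = set(self.resolution) - set(RESOLUTIONS)
        if bad:
            raise ValueError(f"unknown resolution tags: {sorted(map(str, bad))}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.box is not None:
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three strictly positive lengths")
        for i, j in self.exclusions:
            if (j, i) not in self.exclusions:
                raise ValueError(f"exclusion list not symmetric: ({i},{j}) present without ({j},{i})")

    # -- construction helpers -------------------------------------------

    @classmethod
    def create(
        cls,
        positions,
        resolution="UA",
        types="X",
        charges=0.0,
        masses=1.0,
        chains=0,
        resids=None,
        resnames="RES",
        box=None,
        bonds=None,
        bond_r0=0.0,
        bond_k=0.0,
        exclude_from_bonds=True,
    ) -> "ParticleSystem":
        """Build a system, broadcasting scalar metadata over all particles.

        With ``exclude_from_bonds`` the 1-2 and 1-3 neighbour pairs implied
        by the bond list are added to the nonbonded exclusion list
        (standard practice for bonded toy systems).
        """
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(positions)

        def _bcast(val, dtype=object):
            arr = np.asarray(val, dtype=dtype)
            if arr.ndim == 0:
                arr = np.full(n, val, dtype=dtype)
            return arr

        if resids is None:
            resids = np.arange(n)
        bonds = np.zeros((0, 2), dtype=int) if bonds is None else np.asarray(bonds, dtype=int).reshape(-1, 2)
        m = len(bonds)
        bond_r0 = np.broadcast_to(np.asarray(bond_r0, dtype=float), (m,)).copy()
        bond_k = np.broadcast_to(np.asarray(bond_k, dtype=float), (m,)).copy()
        exclusions = exclusions_from_bonds(bonds) if exclude_from_bonds else frozenset()
        return cls(
            positions=positions,
            resolution=_bcast(resolution),
            types=_bcast(types),
            charges=_bcast(charges, float),
            masses=_bcast(masses, float),
            chains=_bcast(chains, int),
            resids=_bcast(resids, int),
            resnames=_bcast(resnames),
            box=box,
            exclusions=exclusions,
            bonds=bonds,
            bond_r0=bond_r0,
            bond_k=bond_k,
        )

    # -- convenience -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def with_positions(self, positions: np.ndarray) -> "ParticleSystem":
        """Copy of the system with replaced coordinates."""
        return replace(self, positions=np.asarray(positions, dtype=float))

    def chain_indices(self, chain: int) -> np.ndarray:
        return np.flatnonzero(self.chains == chain)

    def center_of_mass(self, indices=None) -> np.ndarray:
        idx = slice(None) if indices is None else np.asarray(indices)
        m = self.masses[idx]
        return (self.positions[idx] * m[:, None]).sum(axis=0) / m.sum()


def exclusions_from_bonds(bonds: np.ndarray) -> frozenset:
    """Symmetric 1-2 and 1-3 exclusion set implied by a harmonic bond list."""
    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    neigh: dict[int, set[int]] = {}
    for i, j in bonds:
        neigh.setdefault(int(i), set()).add(int(j))
        neigh.setdefault(int(j), set()).add(int(i))
    excl = set()
    for i, j in bonds:
        excl.add((int(i), int(j)))
        excl.add((int(j), int(i)))
    for j, partners in neigh.items():
        for i in partners:
            for k in partners:
                if i != k:
                    excl.add((i, k))
                    excl.add((k, i))
    return frozenset(excl)


def minimum_image(vectors: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Orthorhombic boxes only; with ``box=None`` vectors pass through.
    """
    if box is None:
        return vectors
    return vectors - box * np.round(vectors / box)
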