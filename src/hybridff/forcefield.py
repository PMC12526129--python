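"""Hybrid-resolution nonbonded energy model.

The total potential of a mixed united-atom (UA) / coarse-grained (CG)
system decomposes exactly into three terms,

    U_total = U_UA + U_CG + U_UA-CG,

where each nonbonded pair is routed by the resolution tags of its two
particles.  Pair interactions are 12-6 Lennard-Jones plus reaction-field
Coulomb; two global, dimensionless scaling factors modulate LJ well
depths: ``eps_cg`` multiplies every CG-CG well depth and ``eps_dual``
every cross-resolution (UA-CG) well depth.  UA-UA terms are never scaled,
and sigma is never modified — the scaling layer tunes interaction
*strength* after pair-specific excluded volume has been fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .system import ParticleSystem, minimum_image
from .units import F_COULOMB


class ParameterLookupError(KeyError):
    """A type-label pair does not resolve in the pair table."""


# ---------------------------------------------------------------------------
# elementary pair interactions
# ---------------------------------------------------------------------------

def lj_energy(r, epsilon, sigma):
    """12-6 Lennard-Jones energy 4*eps*[(sigma/r)^12 - (sigma/r)^6].

    Parameters are the well depth ``epsilon`` (kJ/mol, >= 0) and the zero
    crossing ``sigma`` (nm, > 0).  The minimum sits at r = 2^(1/6)*sigma
    with value -epsilon.  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance r must be positive")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    if np.any(np.asarray(epsilon) < 0):
        raise ValueError("epsilon must be nonnegative")
    sr6 = (sigma / r) ** 6
    out = 4.0 * epsilon * (sr6 * sr6 - sr6)
    return out if out.ndim else float(out)


def lj_force_magnitude(r, epsilon, sigma):
    """-dU/dr of the 12-6 potential (positive = repulsive push apart)."""
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (12.0 * sr6 * sr6 - 6.0 * sr6) / r


def reaction_field_constants(cutoff: float, eps_r: float, eps_rf: float | None):
    """(k_rf, c_rf) for the shifted reaction-field potential.

    ``eps_rf=None`` means a conducting (infinite-dielectric) boundary,
    the MARTINI convention.  The shift constant c_rf zeroes the potential
    at the cutoff, making the energy continuous there.
    """
    if eps_rf is None or math.isinf(eps_rf):
        k_rf = 1.0 / (2.0 * cutoff**3)
    else:
        k_rf = (eps_rf - eps_r) / (2.0 * eps_rf + eps_r) / cutoff**3
    c_rf = 1.0 / cutoff + k_rf * cutoff**2
    return k_rf, c_rf


def coulomb_reaction_field(r, q1, q2, cutoff=1.2, eps_r=15.0, eps_rf=None):
    """Shifted reaction-field Coulomb energy in kJ/mol.

    U(r) = f*q1*q2/eps_r * (1/r + k_rf*r^2 - c_rf) for r <= cutoff and 0
    beyond; the shift makes U(cutoff) = 0 exactly.  Symmetric under charge
    swap.  ``r <= 0`` is a domain error; ``r > cutoff`` returns 0 by
    contract (outside interaction range).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance r must be positive")
    k_rf, c_rf = reaction_field_constants(cutoff, eps_r, eps_rf)
    pref = F_COULOMB * (q1 * q2) / eps_r
    u = np.where(r <= cutoff, pref * (1.0 / r + k_rf * r**2 - c_rf), 0.0)
    return u if u.ndim else float(u)


def combine_lorentz_berthelot(eps_i, sigma_i, eps_j, sigma_j):
    """Lorentz-Berthelot combining rule: geometric eps, arithmetic sigma."""
    if eps_i < 0 or eps_j < 0:
        raise ValueError("epsilon must be nonnegative")
    if sigma_i <= 0 or sigma_j <= 0:
        raise ValueError("sigma must be positive")
    return math.sqrt(eps_i * eps_j), 0.5 * (sigma_i + sigma_j)


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------

@dataclass
class HybridPairTable:
    """Per-pair LJ parameters, charges, and the global scaling layer.

    ``pairs`` maps an (unordered) type-label pair to (epsilon, sigma);
    lookup is symmetric and alias labels resolve transparently.  Missing
    pairs fall back to Lorentz-Berthelot combination of the self terms
    when both are stored.

    ``eps_cg`` scales CG-CG LJ well depths; ``eps_dual`` scales UA-CG
    well depths; UA-UA terms are untouched and sigma never changes.
    ``scale_cg_coulomb`` optionally extends ``eps_cg`` to CG-CG Coulomb
    terms (off by default: rescaling practice modifies LJ epsilon and no
    dielectric change is implied).
    """

    pairs: dict = field(default_factory=dict)
    charges: dict = field(default_factory=dict)
    eps_cg: float = 0.2
    eps_dual: float = 0.8
    cutoff: float = 1.2
    eps_r: float = 15.0
    eps_rf: float | None = None
    scale_cg_coulomb: bool = False
    shift_lj: bool = True
    aliases: dict = field(default_factory=dict)

    def __post_init__(self):
        canon = {}
        for (a, b), (eps, sigma) in self.pairs.items():
            if eps < 0:
                raise ValueError(f"epsilon < 0 for pair ({a},{b})")
            if sigma <= 0:
                raise ValueError(f"sigma <= 0 for pair ({a},{b})")
            canon[self._key(a, b)] = (float(eps), float(sigma))
        self.pairs = canon
        for name, bound in (("eps_cg", self.eps_cg), ("eps_dual", self.eps_dual)):
            if not (0.0 < bound <= 2.0):
                raise ValueError(f"{name} must lie in (0, 2], got {bound}")

    # -- lookup ----------------------------------------------------------

    def _resolve(self, label: str) -> str:
        seen = set()
        while label in self.aliases:
            if label in seen:
                raise ParameterLookupError(f"alias cycle at {label!r}")
            seen.add(label)
            label = self.aliases[label]
        return label

    @staticmethod
    def _key(a: str, b: str):
        return (a, b) if a <= b else (b, a)

    def lookup(self, a: str, b: str):
        """Stored (epsilon, sigma) for a type pair, symmetric in (a, b)."""
        a, b = self._resolve(a), self._resolve(b)
        key = self._key(a, b)
        if key in self.pairs:
            return self.pairs[key]
        ka, kb = self._key(a, a), self._key(b, b)
        if ka in self.pairs and kb in self.pairs:
            ea, sa = self.pairs[ka]
            eb, sb = self.pairs[kb]
            return combine_lorentz_berthelot(ea, sa, eb, sb)
        raise ParameterLookupError(f"no LJ parameters for pair ({a!r}, {b!r})")

    def charge(self, label: str) -> float:
        return float(self.charges.get(self._resolve(label), 0.0))

    def set_pair(self, a: str, b: str, eps: float, sigma: float) -> None:
        if eps < 0 or sigma <= 0:
            raise ValueError("need eps >= 0 and sigma > 0")
        self.pairs[self._key(self._resolve(a), self._resolve(b))] = (float(eps), float(sigma))

    # -- scaling ---------------------------------------------------------

    def lj_scale(self, res_a: str, res_b: str) -> float:
        """LJ well-depth multiplier for a pair of resolution tags."""
        if res_a == "CG" and res_b == "CG":
            return self.eps_cg
        if res_a != res_b:
            return self.eps_dual
        return 1.0

    def coulomb_scale(self, res_a: str, res_b: str) -> float:
        if self.scale_cg_coulomb and res_a == "CG" and res_b == "CG":
            return self.eps_cg
        return 1.0

    def effective_pair(self, a: str, b: str, res_a: str, res_b: str):
        """(epsilon, sigma) after the resolution-dependent scaling layer."""
        eps, sigma = self.lookup(a, b)
        return eps * self.lj_scale(res_a, res_b), sigma

    def unscaled(self) -> "HybridPairTable":
        return replace(self, pairs=dict(self.pairs), eps_cg=1.0, eps_dual=1.0)


def apply_scaling(table: HybridPairTable, resolutions: dict) -> dict:
    """Effective LJ parameters for every stored pair under a tag map.

    ``resolutions`` maps type label -> "UA"/"CG".  Returns
    {(a, b): (eps_effective, sigma)} with CG-CG depths multiplied by
    ``eps_cg``, UA-CG depths by ``eps_dual`` and UA-UA depths untouched;
    sigma is never modified.
    """
    out = {}
    for (a, b), (eps, sigma) in table.pairs.items():
        scale = table.lj_scale(resolutions[a], resolutions[b])
        out[(a, b)] = (eps * scale, sigma)
    return out


# ---------------------------------------------------------------------------
# system-level energies
# ---------------------------------------------------------------------------

@dataclass
class EnergyDecomposition:
    """Three-way split of the nonbonded energy with LJ/Coulomb sub-totals."""

    u_ua_lj: float = 0.0
    u_ua_coulomb: float = 0.0
    u_cg_lj: float = 0.0
    u_cg_coulomb: float = 0.0
    u_cross_lj: float = 0.0
    u_cross_coulomb: float = 0.0

    @property
    def u_ua(self) -> float:
        return self.u_ua_lj + self.u_ua_coulomb

    @property
    def u_cg(self) -> float:
        return self.u_cg_lj + self.u_cg_coulomb

    @property
    def u_cross(self) -> float:
        return self.u_cross_lj + self.u_cross_coulomb

    @property
    def u_total(self) -> float:
        return self.u_ua + self.u_cg + self.u_cross


class PairModel:
    """Precomputed per-pair parameter matrices for fast energy/force loops.

    Resolves every type pair once against the table (raising
    :class:`ParameterLookupError` with the offending label) and stores
    dense N x N matrices of effective epsilon, sigma and charge products
    plus the exclusion mask.  Intended for the small systems the toy
    samplers handle.
    """

    def __init__(self, system: ParticleSystem, table: HybridPairTable):
        n = len(system)
        self.system = system
        self.table = table
        self.cutoff = table.cutoff
        eps = np.zeros((n, n))
        sig = np.ones((n, n))
        qq = np.zeros((n, n))
        for a in set(system.types):
            try:
                table.lookup(a, a)
            except ParameterLookupError:
                raise ParameterLookupError(f"type label {a!r} has no parameters in the pair table")
        res = system.resolution
        types = system.types
        charges = system.charges
        for i in range(n):
            for j in range(i + 1, n):
                e, s = table.effective_pair(types[i], types[j], res[i], res[j])
                eps[i, j] = eps[j, i] = e
                sig[i, j] = sig[j, i] = s
                cscale = table.coulomb_scale(res[i], res[j])
                qq[i, j] = qq[j, i] = charges[i] * charges[j] * cscale
        mask = ~np.eye(n, dtype=bool)
        for i, j in system.exclusions:
            mask[i, j] = False
        self.eps, self.sig, self.qq, self.mask = eps, sig, qq, mask
        # pair category matrices for the decomposition
        is_cg = np.asarray([r == "CG" for r in res])
        self.cat_cg = np.outer(is_cg, is_cg)
        self.cat_ua = np.outer(~is_cg, ~is_cg)
        self.cat_cross = ~(self.cat_cg | self.cat_ua)
        self.k_rf, self.c_rf = reaction_field_constants(table.cutoff, table.eps_r, table.eps_rf)
        self.coul_pref = F_COULOMB / table.eps_r

    # -- geometry --------------------------------------------------------

    def _pair_geometry(self, positions):
        d = positions[:, None, :] - positions[None, :, :]
        d = minimum_image(d, self.system.box)
        r = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(r, np.inf)
        return d, r

    # -- energies --------------------------------------------------------

    def pair_energy_matrices(self, positions):
        """(U_lj, U_coulomb) N x N matrices (each pair counted twice)."""
        _, r = self._pair_geometry(positions)
        within = self.mask & (r < self.cutoff)
        rr = np.where(within, r, 1.0)
        sr6 = np.where(within, (self.sig / rr) ** 6, 0.0)
        u_lj = 4.0 * self.eps * (sr6 * sr6 - sr6)
        if self.table.shift_lj:
            src6 = (self.sig / self.cutoff) ** 6
            u_lj -= np.where(within, 4.0 * self.eps * (src6 * src6 - src6), 0.0)
        u_lj = np.where(within, u_lj, 0.0)
        u_c = self.coul_pref * self.qq * (1.0 / rr + self.k_rf * rr**2 - self.c_rf)
        u_c = np.where(within, u_c, 0.0)
        return u_lj, u_c

    def energy_decomposition(self, positions=None) -> EnergyDecomposition:
        pos = self.system.positions if positions is None else positions
        u_lj, u_c = self.pair_energy_matrices(pos)

        def _half(mat, cat):
            return 0.5 * float(np.sum(mat[cat]))

        return EnergyDecomposition(
            u_ua_lj=_half(u_lj, self.cat_ua),
            u_ua_coulomb=_half(u_c, self.cat_ua),
            u_cg_lj=_half(u_lj, self.cat_cg),
            u_cg_coulomb=_half(u_c, self.cat_cg),
            u_cross_lj=_half(u_lj, self.cat_cross),
            u_cross_coulomb=_half(u_c, self.cat_cross),
        )

    def nonbonded_energy(self, positions=None) -> float:
        return self.energy_decomposition(positions).u_total

    def bonded_energy(self, positions=None) -> float:
        pos = self.system.positions if positions is None else positions
        s = self.system
        if len(s.bonds) == 0:
            return 0.0
        d = minimum_image(pos[s.bonds[:, 0]] - pos[s.bonds[:, 1]], s.box)
        r = np.linalg.norm(d, axis=-1)
        return float(np.sum(0.5 * s.bond_k * (r - s.bond_r0) ** 2))

    def potential_energy(self, positions=None) -> float:
        return self.nonbonded_energy(positions) + self.bonded_energy(positions)

    # -- forces ----------------------------------------------------------

    def forces(self, positions=None) -> np.ndarray:
        """Analytic forces in kJ mol^-1 nm^-1 (LJ + RF Coulomb + bonds)."""
        s = self.system
        pos = s.positions if positions is None else positions
        d, r = self._pair_geometry(pos)
        within = self.mask & (r < self.cutoff)
        rr = np.where(within, r, 1.0)
        sr6 = np.where(within, (self.sig / rr) ** 6, 0.0)
        # -dU/dr for LJ (shift does not change forces) and RF Coulomb
        f_lj = 4.0 * self.eps * (12.0 * sr6 * sr6 - 6.0 * sr6) / rr
        f_c = self.coul_pref * self.qq * (1.0 / rr**2 - 2.0 * self.k_rf * rr)
        fmag = np.where(within, f_lj + f_c, 0.0)
        f = np.einsum("ij,ijk->ik", fmag / rr, d)
        if len(s.bonds) > 0:
            db = minimum_image(pos[s.bonds[:, 0]] - pos[s.bonds[:, 1]], s.box)
            rb = np.linalg.norm(db, axis=-1)
            fb = (-s.bond_k * (rb - s.bond_r0) / rb)[:, None] * db
            np.add.at(f, s.bonds[:, 0], fb)
            np.add.at(f, s.bonds[:, 1], -fb)
        if not np.all(np.isfinite(f)):
            bad = int(np.flatnonzero(~np.isfinite(f).all(axis=1))[0])
            raise FloatingPointError(f"non-finite force on particle {bad}")
        return f


def energy_decomposition(system: ParticleSystem, table: HybridPairTable) -> EnergyDecomposition:
    """Three-way nonbonded energy split U_total = U_UA + U_CG + U_UA-CG.

    Sums LJ + reaction-field Coulomb over all non-excluded pairs within
    the cutoff (minimum image when the system carries a box), routing each
    pair by its two resolution tags.  The decomposition identity holds
    exactly because each pair is assigned to exactly one term.
    """
    return PairModel(system, table).energy_decomposition()


def pair_potential(table: HybridPairTable, type_a: str, type_b: str, res_a: str = "UA", res_b: str = "CG"):
    """Scalar effective pair potential U(r) for an isolated dimer.

    Returns a vectorised callable combining the scaled LJ term (shifted at
    the cutoff if the table says so) and reaction-field Coulomb.
    """
    eps, sigma = table.effective_pair(type_a, type_b, res_a, res_b)
    qa, qb = table.charge(type_a), table.charge(type_b)
    cscale = table.coulomb_scale(res_a, res_b)
    cutoff = table.cutoff
    shift = 0.0
    if table.shift_lj:
        shift = lj_energy(cutoff, eps, sigma) if eps > 0 else 0.0

    def u(r):
        r = np.asarray(r, dtype=float)
        inside = r < cutoff
        out = np.where(inside, lj_energy(np.where(r > 0, r, 1.0), eps, sigma) - shift, 0.0)
        if qa * qb != 0.0:
            out = out + coulomb_reaction_field(
                np.where(r > 0, r, 1.0), qa * cscale, qb, cutoff, table.eps_r, table.eps_rf
            ) * inside
        return out if out.ndim else float(out)

    return u
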