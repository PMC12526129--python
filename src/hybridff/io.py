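"""Readers and writers for on-disk formats.

Coordinate files (PDB, GRO, XYZ) go through MDAnalysis; all positions
are converted to the internal nm convention on the way in (MDAnalysis
normalises to angstrom) and back on the way out.  The pair-parameter
table, umbrella-window series and run configuration are small
whitespace-delimited text dialects defined here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .forcefield import HybridPairTable
from .sampler import UmbrellaWindow
from .system import ParticleSystem


class ParseError(ValueError):
    """A file could not be parsed; the message carries file context."""


_FORMATS = ("PDB", "GRO", "XYZ")


def _format_from_path(path, fmt=None) -> str:
    if fmt is not None:
        fmt = fmt.upper()
    else:
        fmt = Path(path).suffix.lstrip(".").upper()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported coordinate format {fmt!r}; choose from {_FORMATS}")
    return fmt


def read_coordinates(
    path,
    fmt: str | None = None,
    resolution_map=None,
    default_resolution: str = "UA",
    charges=None,
    masses=None,
) -> ParticleSystem:
    """Read a PDB/GRO/XYZ file into a :class:`ParticleSystem` (nm).

    Resolution tags are assigned by looking each atom name up in
    ``resolution_map`` (falling back to ``default_resolution``) — the
    coordinate formats themselves carry no resolution notion.  Chain ids
    come from segment/chain records when present, else from blocks of
    non-decreasing residue numbers.  Malformed files raise
    :class:`ParseError` with the file name and the underlying complaint.
    """
    import MDAnalysis as mda

    fmt = _format_from_path(path, fmt)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
            atoms = u.atoms
            positions = atoms.positions / 10.0  # angstrom -> nm
    except Exception as exc:
        n_good = _count_good_atom_lines(path, fmt)
        raise ParseError(
            f"could not parse {path.name} as {fmt} "
            f"(last good atom record: {n_good}): {exc}"
        ) from exc
    n = len(atoms)
    names = getattr(atoms, "names", np.array(["X"] * n, dtype=object))
    try:
        resids = np.asarray(atoms.resids) - 1  # file convention 1-based -> internal 0-based
        resnames = np.asarray(atoms.resnames, dtype=object)
    except mda.exceptions.NoDataError:
        resids = np.zeros(n, dtype=int)
        resnames = np.array(["RES"] * n, dtype=object)
    chains = _chain_ids(atoms, resids)
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    resolution_map = resolution_map or {}
    resolution = np.array(
        [resolution_map.get(str(nm), default_resolution) for nm in names], dtype=object
    )
    charges = np.zeros(n) if charges is None else np.broadcast_to(np.asarray(charges, float), (n,)).copy()
    masses = np.ones(n) if masses is None else np.broadcast_to(np.asarray(masses, float), (n,)).copy()
    return ParticleSystem(
        positions=positions,
        resolution=resolution,
        types=np.asarray([str(x) for x in names], dtype=object),
        charges=charges,
        masses=masses,
        chains=chains,
        resids=resids.astype(int),
        resnames=resnames,
        box=box,
    )


def _chain_ids(atoms, resids) -> np.ndarray:
    try:
        segids = atoms.chainIDs
    except Exception:
        try:
            segids = atoms.segids
        except Exception:
            segids = None
    if segids is not None and len(set(segids)) > 1:
        mapping = {s: i for i, s in enumerate(dict.fromkeys(segids))}
        return np.array([mapping[s] for s in segids], dtype=int)
    # fall back: a new chain starts when the residue number decreases
    chains = np.zeros(len(resids), dtype=int)
    current = 0
    for i in range(1, len(resids)):
        if resids[i] < resids[i - 1]:
            current += 1
        chains[i] = current
    return chains


def _count_good_atom_lines(path, fmt) -> int:
    """Best-effort count of well-formed atom records before a failure."""
    count = 0
    try:
        with open(path, errors="replace") as fh:
            for line in fh:
                if fmt == "PDB" and line.startswith(("ATOM", "HETATM")) and len(line.rstrip()) >= 54:
                    count += 1
                elif fmt == "GRO" and len(line.rstrip()) >= 44 and line[:5].strip().isdigit():
                    count += 1
                elif fmt == "XYZ" and len(line.split()) == 4:
                    count += 1
    except OSError:
        pass
    return count


def write_coordinates(system: ParticleSystem, path, fmt: str | None = None) -> None:
    """Write a system to PDB/GRO/XYZ via MDAnalysis (internal nm -> file units)."""
    import MDAnalysis as mda

    fmt = _format_from_path(path, fmt)
    n = len(system)
    resindex, resids_u, resnames_u, chains_u = _residue_tables(system)
    u = mda.Universe.empty(
        n,
        n_residues=len(resids_u),
        n_segments=len(set(chains_u)),
        atom_resindex=resindex,
        residue_segindex=[sorted(set(chains_u)).index(c) for c in chains_u],
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(t) for t in system.types])
    u.add_TopologyAttr("resnames", [str(r) for r in resnames_u])
    u.add_TopologyAttr("resids", (np.asarray(resids_u) + 1).tolist())
    u.add_TopologyAttr("chainIDs", [chr(ord("A") + int(c) % 26) for c in system.chains])
    u.add_TopologyAttr("elements", ["C"] * n)
    u.atoms.positions = system.positions * 10.0
    if system.box is not None:
        u.dimensions = [*(system.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _residue_tables(system: ParticleSystem):
    keys = list(zip(system.chains.tolist(), system.resids.tolist()))
    uniq = list(dict.fromkeys(keys))
    index_of = {k: i for i, k in enumerate(uniq)}
    resindex = [index_of[k] for k in keys]
    resids_u = [k[1] for k in uniq]
    chains_u = [k[0] for k in uniq]
    resnames_u = []
    seen = set()
    for k, rn in zip(keys, system.resnames):
        if k not in seen:
            seen.add(k)
            resnames_u.append(rn)
    return np.asarray(resindex), resids_u, resnames_u, chains_u


# ---------------------------------------------------------------------------
# pair-parameter tables
# ---------------------------------------------------------------------------

def read_pair_table(path) -> HybridPairTable:
    """Read the whitespace-delimited pair-parameter dialect.

    Row grammar (``#`` starts a comment)::

        type_i type_j epsilon_kJmol sigma_nm    # LJ pair row
        charge <type> <q_e>                     # per-type charge
        alias <new_label> <existing_label>      # e.g. alias BB_P5 ASN
        set <key> <value>                       # eps_cg, eps_dual, cutoff,
                                                # eps_r, eps_rf, scale_cg_coulomb

    Duplicate pair rows with conflicting values are an error listing both
    line numbers.
    """
    pairs: dict = {}
    pair_lines: dict = {}
    charges: dict = {}
    aliases: dict = {}
    settings: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] == "charge":
                if len(tok) != 3:
                    raise ParseError(f"{path}:{lineno}: charge rows need 'charge TYPE Q'")
                charges[tok[1]] = float(tok[2])
            elif tok[0] == "alias":
                if len(tok) != 3:
                    raise ParseError(f"{path}:{lineno}: alias rows need 'alias NEW EXISTING'")
                aliases[tok[1]] = tok[2]
            elif tok[0] == "set":
                if len(tok) != 3:
                    raise ParseError(f"{path}:{lineno}: set rows need 'set KEY VALUE'")
                settings[tok[1]] = tok[2]
            elif len(tok) == 4:
                a, b = tok[0], tok[1]
                try:
                    eps, sigma = float(tok[2]), float(tok[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad numeric field: {exc}") from exc
                if eps < 0:
                    raise ParseError(f"{path}:{lineno}: epsilon must be nonnegative")
                if sigma <= 0:
                    raise ParseError(f"{path}:{lineno}: sigma must be positive")
                key = (a, b) if a <= b else (b, a)
                if key in pairs and pairs[key] != (eps, sigma):
                    raise ParseError(
                        f"{path}:{lineno}: conflicting duplicate for pair {key}, "
                        f"first defined at line {pair_lines[key]}"
                    )
                pairs[key] = (eps, sigma)
                pair_lines[key] = lineno
            else:
                raise ParseError(f"{path}:{lineno}: unrecognised row: {line!r}")
    kwargs = {}
    for key, cast in (
        ("eps_cg", float), ("eps_dual", float), ("cutoff", float),
        ("eps_r", float), ("scale_cg_coulomb", lambda v: v.lower() in ("1", "true", "yes")),
        ("shift_lj", lambda v: v.lower() in ("1", "true", "yes")),
    ):
        if key in settings:
            kwargs[key] = cast(settings.pop(key))
    if "eps_rf" in settings:
        v = settings.pop("eps_rf")
        kwargs["eps_rf"] = None if v.lower() in ("inf", "none") else float(v)
    if settings:
        raise ParseError(f"{path}: unknown settings {sorted(settings)}")
    return HybridPairTable(pairs=pairs, charges=charges, aliases=aliases, **kwargs)


def write_pair_table(table: HybridPairTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# type_i type_j epsilon_kJmol sigma_nm\n")
        for (a, b), (eps, sigma) in sorted(table.pairs.items()):
            fh.write(f"{a} {b} {eps:.6g} {sigma:.6g}\n")
        for t, q in sorted(table.charges.items()):
            fh.write(f"charge {t} {q:.6g}\n")
        for new, old in sorted(table.aliases.items()):
            fh.write(f"alias {new} {old}\n")
        fh.write(f"set eps_cg {table.eps_cg:.6g}\n")
        fh.write(f"set eps_dual {table.eps_dual:.6g}\n")
        fh.write(f"set cutoff {table.cutoff:.6g}\n")
        fh.write(f"set eps_r {table.eps_r:.6g}\n")
        fh.write(f"set eps_rf {'inf' if table.eps_rf is None else table.eps_rf}\n")
        fh.write(f"set scale_cg_coulomb {str(table.scale_cg_coulomb).lower()}\n")
        fh.write(f"set shift_lj {str(table.shift_lj).lower()}\n")


# ---------------------------------------------------------------------------
# umbrella-window files
# ---------------------------------------------------------------------------

def write_window(window: UmbrellaWindow, path) -> None:
    """Columnar window dialect: metadata header plus `step r_nm` rows."""
    with open(path, "w") as fh:
        fh.write(
            f"# center_nm={window.center:.8g} k_kJmol_nm2={window.force_constant:.8g} "
            f"seed={window.seed} discard={window.discard}\n"
        )
        fh.write("# step r_nm\n")
        for i, r in enumerate(window.samples):
            fh.write(f"{i} {r:.8f}\n")


def read_window(path) -> UmbrellaWindow:
    meta = {}
    samples = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            if not line:
                continue
            tok = line.split()
            if len(tok) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'step r_nm'")
            samples.append(float(tok[1]))
    if "center_nm" not in meta or "k_kJmol_nm2" not in meta:
        raise ParseError(f"{path}: window header missing center_nm/k_kJmol_nm2")
    return UmbrellaWindow(
        center=float(meta["center_nm"]),
        force_constant=float(meta["k_kJmol_nm2"]),
        samples=np.asarray(samples),
        discard=int(meta.get("discard", 0)),
        seed=int(meta.get("seed", 0)),
    )


def read_window_directory(directory) -> list[UmbrellaWindow]:
    """All `*.win` files in a directory, ordered by bias centre."""
    paths = sorted(Path(directory).glob("*.win"))
    if not paths:
        raise FileNotFoundError(f"no .win files in {directory}")
    windows = [read_window(p) for p in paths]
    windows.sort(key=lambda w: w.center)
    return windows


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "pair_table": str,
    "eps_cg": float,
    "eps_dual": float,
    "cutoff": float,
    "temperature": float,
    "friction": float,
    "timestep": float,
    "n_steps": int,
    "seed": int,
    "cluster_cutoff": float,
    "encounter_threshold": float,
    "output_dir": str,
    "log_level": str,
}


@dataclass
class RunConfig:
    """Flat, fully serialisable run configuration; unknown keys rejected."""

    pair_table: str = ""
    eps_cg: float = 0.2
    eps_dual: float = 0.8
    cutoff: float = 1.2
    temperature: float = 310.0
    friction: float = 2.0
    timestep: float = 0.01
    n_steps: int = 10000
    seed: int = 0
    cluster_cutoff: float = 0.6
    encounter_threshold: float = 30.0
    output_dir: str = "."
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat `key = value` (TOML-subset) config file."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - set(_CONFIG_KEYS)
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs = {k: _CONFIG_KEYS[k](v) for k, v in data.items()}
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key in _CONFIG_KEYS:
                value = getattr(self, key)
                if isinstance(value, str):
                    fh.write(f'{key} = "{value}"\n')
                else:
                    fh.write(f"{key} = {value}\n")

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("extras", None)
        return json.dumps(d, indent=2, sort_keys=True)
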