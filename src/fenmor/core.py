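"""Domain types and I/O shared by all analysis stages.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Atom` records (author residue numbering, hydrogens retained but
flagged), a :class:`Trajectory` is a fixed topology plus a stack of coordinate
frames, and a :class:`Selection` is an ordered set of atom indices produced by
a tiny conjunctive query language (``"resid 147 and sidechain and heavy"``).

PDB files are parsed with :mod:`gemmi`; trajectories can be multi-model PDB or
a plain whitespace table ``frame atom_index x y z`` (one row per atom per
frame), so nothing binary is ever required.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "LigandGroupMap",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "select",
    "parse_resid_spec",
]

#: backbone heavy-atom names; everything else (minus backbone hydrogens) is sidechain
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})
#: hydrogens bonded to backbone atoms
BACKBONE_HYDROGENS = frozenset({"H", "H1", "H2", "H3", "HN", "HA", "HA2", "HA3", "HXT"})


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from an atom name (PDB convention)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass(frozen=True, eq=False)
class Atom:
    """One atom record with author numbering preserved."""

    name: str
    element: str
    residue_seq: int
    residue_name: str
    chain: str
    position: np.ndarray  # (3,) Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def mass(self) -> float:
        el = gemmi.Element(self.element)
        return el.weight if el.weight > 0 else 12.011


class Structure:
    """An ordered collection of atoms for a single frame.

    ``(chain, residue_seq, name)`` must be unique; altloc resolution happens
    at parse time (highest occupancy wins, ties go to 'A').
    """

    def __init__(self, atoms: Sequence[Atom], id: str = "structure"):
        if not atoms:
            raise ValueError("Structure must contain at least one atom")
        self.atoms = list(atoms)
        self.id = id
        keys = [(a.chain, a.residue_seq, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom key {dup} in structure {id!r}")
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [
            Atom(a.name, a.element, a.residue_seq, a.residue_name, a.chain, xyz)
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, id=id or self.id)

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique ``(chain, resid, resname)`` triples in order of appearance."""
        out: list[tuple[str, int, str]] = []
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.residue_seq, a.residue_name)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out


@dataclass(frozen=True)
class Selection:
    """Ordered, unique atom indices into a Structure."""

    atom_indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.atom_indices)
        if len(set(idx)) != len(idx):
            raise ValueError(f"selection {self.label!r}: duplicate indices")
        if any(i < 0 for i in idx):
            raise ValueError(f"selection {self.label!r}: negative index")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.array(self.atom_indices, dtype=int)


class Trajectory:
    """A fixed topology plus an ordered stack of coordinate frames."""

    def __init__(self, topology: Structure, frames: Sequence[np.ndarray], frame_interval: float = 1.0):
        if frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 (ns)")
        if len(frames) == 0:
            raise ValueError("Trajectory must contain at least one frame")
        n = len(topology)
        stack = []
        for i, f in enumerate(frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {i}: coordinate shape {f.shape} != ({n}, 3)")
            stack.append(f)
        self.topology = topology
        self.frames = np.array(stack)  # (F, n, 3)
        self.frame_interval = float(frame_interval)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i], id=f"{self.topology.id}[frame {i}]")


class LigandGroupMap:
    """Ligand substituent groups (e.g. piperidine, phenethyl, phenyl,
    propanamide) as atom-name sets, plus the protonatable amine atom."""

    def __init__(self, groups: Mapping[str, Iterable[str]], amine_atom: str,
                 allow_overlap: bool = False):
        self.groups = {g: frozenset(names) for g, names in groups.items()}
        self.amine_atom = amine_atom
        if not allow_overlap:
            all_names: set[str] = set()
            for g, names in self.groups.items():
                clash = all_names & names
                if clash:
                    raise ValueError(f"group {g!r} overlaps earlier groups on {sorted(clash)}")
                all_names |= names
        holders = [g for g, names in self.groups.items() if amine_atom in names]
        if len(holders) != 1:
            raise ValueError(f"amine atom {amine_atom!r} must belong to exactly one group, found {holders}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "groups": {g: sorted(n) for g, n in self.groups.items()},
            "amine_atom": self.amine_atom,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LigandGroupMap":
        payload = json.loads(Path(path).read_text())
        return cls(payload["groups"], payload["amine_atom"])


# ---------------------------------------------------------------------------
# PDB / trajectory I/O
# ---------------------------------------------------------------------------

def _convert_model(model: gemmi.Model, id: str) -> Structure:
    atoms: list[Atom] = []
    best: dict[tuple[str, int, str], tuple[float, str, Atom]] = {}
    for chain in model:
        for res in chain:
            for at in res:
                key = (chain.name, res.seqid.num, at.name)
                element = at.element.name if at.element.name else _element_from_name(at.name)
                rec = Atom(at.name, element, res.seqid.num, res.name, chain.name,
                           np.array([at.pos.x, at.pos.y, at.pos.z]))
                alt = at.altloc if at.altloc else "A"
                prev = best.get(key)
                # altloc policy: highest occupancy wins, ties resolved toward 'A'
                if prev is None or (at.occ, -ord(alt)) > (prev[0], -ord(prev[1])):
                    if prev is None:
                        atoms.append(rec)
                        best[key] = (at.occ, alt, rec)
                    else:
                        atoms[atoms.index(prev[2])] = rec
                        best[key] = (at.occ, alt, rec)
    return Structure(atoms, id=id)


def read_pdb(path: str | Path, model_index: int = 0) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``model_index`` is 0-based; author residue numbering is preserved and
    hydrogens are retained (``Atom.is_heavy`` distinguishes them).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB {path}: {exc}") from exc
    if model_index < 0 or model_index >= len(st):
        raise IndexError(f"model index {model_index} out of range: {path} has {len(st)} model(s)")
    return _convert_model(st[model_index], id=path.stem)


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a structure (single model) or trajectory (multi-model) as PDB."""
    path = Path(path)
    if isinstance(obj, Trajectory):
        topo, frames = obj.topology, obj.frames
    else:
        topo, frames = obj, obj.coords[None]
    lines: list[str] = []
    multi = frames.shape[0] > 1
    for m, coords in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i, (atom, xyz) in enumerate(zip(topo.atoms, coords), start=1):
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {i % 100000:5d} {name:<4.4s} {atom.residue_name:<3.3s} "
                f"{atom.chain[:1]:1s}{atom.residue_seq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2.2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _read_frames_table(path: Path, n_atoms: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 'frame atom_index x y z'")
            rows.append([float(p) for p in parts])
    if not rows:
        raise ValueError(f"{path}: empty frames file")
    table = np.array(rows)
    frame_ids = table[:, 0].astype(int)
    order = np.unique(frame_ids)
    frames = []
    for f in order:
        block = table[frame_ids == f]
        if block.shape[0] != n_atoms:
            raise ValueError(f"frame {f}: {block.shape[0]} atoms, topology has {n_atoms}")
        idx = block[:, 1].astype(int)
        coords = np.empty((n_atoms, 3))
        coords[idx] = block[:, 2:5]
        frames.append(coords)
    return np.array(frames)


def read_trajectory(topology_path: str | Path, frames_path: str | Path,
                    frame_interval: float = 1.0) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a plain frame table.

    The table format is whitespace-separated ``frame atom_index x y z`` with
    0-based atom indices matching the topology PDB's atom order.
    """
    topo = read_pdb(topology_path, model_index=0)
    frames_path = Path(frames_path)
    if frames_path.suffix.lower() in (".pdb", ".ent"):
        st = gemmi.read_structure(str(frames_path), format=gemmi.CoorFormat.Pdb)
        if len(st) == 0:
            raise ValueError(f"{frames_path}: no models")
        frames = []
        for i in range(len(st)):
            model_struct = _convert_model(st[i], id=f"model{i}")
            if len(model_struct) != len(topo):
                raise ValueError(
                    f"frame {i}: {len(model_struct)} atoms, topology has {len(topo)}")
            frames.append(model_struct.coords)
        return Trajectory(topo, frames, frame_interval)
    frames = _read_frames_table(frames_path, len(topo))
    return Trajectory(topo, frames, frame_interval)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write frames as multi-model PDB (``.pdb``) or plain table (anything else)."""
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        write_pdb(traj, path)
        return
    with open(path, "w") as fh:
        fh.write("# frame atom_index x y z\n")
        for f in range(traj.n_frames):
            for i, xyz in enumerate(traj.frames[f]):
                fh.write(f"{f} {i} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

def parse_resid_spec(spec: str) -> list[tuple[int, int]]:
    """Parse ``"52-65,336-347"`` / ``"147"`` into inclusive (lo, hi) ranges."""
    ranges = []
    for chunk in spec.replace(" ", "").split(","):
        if not chunk:
            continue
        if "-" in chunk[1:]:  # allow negative lo
            lo_s, hi_s = chunk.rsplit("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(chunk)
        if hi < lo:
            raise ValueError(f"bad residue range {chunk!r}")
        ranges.append((lo, hi))
    if not ranges:
        raise ValueError(f"empty residue spec {spec!r}")
    return ranges


def _clause_mask(structure: Structure, tokens: list[str]) -> np.ndarray:
    key, args = tokens[0].lower(), tokens[1:]
    n = len(structure)
    mask = np.zeros(n, dtype=bool)
    if key == "resid":
        if not args:
            raise ValueError("'resid' needs arguments")
        ranges = parse_resid_spec(",".join(args))
        for i, a in enumerate(structure.atoms):
            mask[i] = any(lo <= a.residue_seq <= hi for lo, hi in ranges)
    elif key == "name":
        names = {a.upper() for a in args}
        for i, a in enumerate(structure.atoms):
            mask[i] = a.name.upper() in names
    elif key == "resname":
        names = {a.upper() for a in args}
        for i, a in enumerate(structure.atoms):
            mask[i] = a.residue_name.upper() in names
    elif key == "chain":
        ids = set(args)
        for i, a in enumerate(structure.atoms):
            mask[i] = a.chain in ids
    elif key == "sidechain":
        for i, a in enumerate(structure.atoms):
            mask[i] = a.name.upper() not in BACKBONE_NAMES and a.name.upper() not in BACKBONE_HYDROGENS
    elif key == "backbone":
        for i, a in enumerate(structure.atoms):
            mask[i] = a.name.upper() in BACKBONE_NAMES
    elif key == "heavy":
        for i, a in enumerate(structure.atoms):
            mask[i] = a.is_heavy
    elif key == "all":
        mask[:] = True
    else:
        raise ValueError(f"unknown selection keyword {key!r}")
    return mask


def select(structure: Structure, query: str, label: str | None = None) -> Selection:
    """Evaluate a conjunctive selection query against a structure.

    Clauses joined by ``and``: ``resid 52-65,336-347``, ``name CA CB``,
    ``resname ASP``, ``chain A``, ``sidechain``, ``backbone``, ``heavy``,
    ``all``.  Result order follows atom order in the structure; an empty
    result emits a warning rather than failing silently.
    """
    tokens = query.split()
    if not tokens:
        raise ValueError("empty selection query")
    clauses: list[list[str]] = [[]]
    for tok in tokens:
        if tok.lower() == "and":
            if not clauses[-1]:
                raise ValueError(f"dangling 'and' in query {query!r}")
            clauses.append([])
        else:
            clauses[-1].append(tok)
    if not clauses[-1]:
        raise ValueError(f"dangling 'and' in query {query!r}")
    mask = np.ones(len(structure), dtype=bool)
    for clause in clauses:
        mask &= _clause_mask(structure, clause)
    idx = tuple(int(i) for i in np.nonzero(mask)[0])
    if not idx:
        warnings.warn(f"selection {query!r} matched no atoms", stacklevel=2)
    return Selection(idx, label=label if label is not None else query)


def sidechain_heavy(structure: Structure, resid: int, chain: str | None = None) -> Selection:
    """Sidechain heavy atoms of one residue (CB onward; empty for glycine)."""
    q = f"resid {resid} and sidechain and heavy"
    if chain is not None:
        q += f" and chain {chain}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return select(structure, q, label=f"sidechain-heavy {resid}")
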