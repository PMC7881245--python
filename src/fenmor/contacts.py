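"""Residue contact-fraction profiles, ligand-group fingerprints, Tanimoto similarity.

A residue is "in contact" in a frame if any of its sidechain heavy atoms lies
within a cutoff (default 4.5 Angstrom) of any ligand heavy atom.  Fractional
profiles over a frame window binarise at a display/analysis threshold
(default 0.25); binary profiles are compared with the Tanimoto coefficient

    S_AB = sum(a_i b_i) / (sum(a_i^2) + sum(b_i^2) - sum(a_i b_i))

over the union of residues in the two profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import LigandGroupMap, Selection, Structure, Trajectory, sidechain_heavy

__all__ = [
    "ResidueId",
    "ContactProfile",
    "BinaryProfile",
    "frame_contact",
    "contact_profile",
    "filter_profile",
    "fingerprint_matrix",
    "tanimoto",
    "tanimoto_matrix",
    "crystal_contact_profile",
]

DEFAULT_CUTOFF = 4.5     # Angstrom, heavy-atom contact criterion
DEFAULT_BINARIZE = 0.25  # contact-fraction threshold for binary profiles
SIGNIFICANT_CONTACT = 0.5  # "stable contact" display threshold


class ResidueId(NamedTuple):
    chain: str
    resid: int
    resname: str

    def label(self) -> str:
        return f"{self.resname}{self.resid}"


@dataclass
class ContactProfile:
    """Residue -> fraction of analysed frames in contact, with provenance."""

    fractions: dict[ResidueId, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for r, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{r.label()}: fraction {f} outside [0, 1]")

    def binarize(self, threshold: float = DEFAULT_BINARIZE) -> "BinaryProfile":
        return BinaryProfile({r: int(f >= threshold) for r, f in self.fractions.items()},
                             threshold_used=threshold)

    def to_frame(self) -> pd.DataFrame:
        rows = [(r.chain, r.resid, r.resname, f) for r, f in self.fractions.items()]
        return pd.DataFrame(rows, columns=["chain", "resid", "resname", "fraction"])


@dataclass
class BinaryProfile:
    """Residue -> {0, 1} contact indicator."""

    values: dict[ResidueId, int]
    threshold_used: float = DEFAULT_BINARIZE

    def __post_init__(self) -> None:
        for r, v in self.values.items():
            if v not in (0, 1):
                raise ValueError(f"{r.label()}: binary profile value must be 0 or 1, got {v}")

    def support(self) -> set[ResidueId]:
        return {r for r, v in self.values.items() if v == 1}


def frame_contact(frame: np.ndarray, residue_sidechain: Selection,
                  ligand_heavy: Selection, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True iff the minimum residue-ligand heavy-atom distance is <= cutoff."""
    if len(residue_sidechain) == 0:
        raise ValueError(f"empty residue selection {residue_sidechain.label!r}")
    if len(ligand_heavy) == 0:
        raise ValueError(f"empty ligand selection {ligand_heavy.label!r}")
    d = cdist(frame[residue_sidechain.indices], frame[ligand_heavy.indices]).min()
    return bool(d <= cutoff)


def _ligand_heavy_indices(topology: Structure, ligand: Selection) -> np.ndarray:
    idx = np.array([i for i in ligand.indices if topology.atoms[i].is_heavy])
    if idx.size == 0:
        raise ValueError("ligand selection has no heavy atoms")
    return idx


def _residue_universe(topology: Structure, residues: Sequence[int | ResidueId] | None,
                      ligand: Selection) -> list[ResidueId]:
    lig_keys = {(topology.atoms[i].chain, topology.atoms[i].residue_seq)
                for i in ligand.indices}
    universe = []
    for chain, resid, resname in topology.residues():
        if (chain, resid) in lig_keys:
            continue
        universe.append(ResidueId(chain, resid, resname))
    if residues is None:
        return universe
    wanted = []
    for r in residues:
        if isinstance(r, ResidueId):
            wanted.append(r)
        else:
            matches = [u for u in universe if u.resid == int(r)]
            if not matches:
                raise KeyError(f"residue {r} not present in structure")
            wanted.extend(matches)
    return wanted


def contact_profile(traj: Trajectory, residues: Sequence[int | ResidueId] | None,
                    ligand: Selection, window: tuple[int, int] | None = None,
                    cutoff: float = DEFAULT_CUTOFF) -> ContactProfile:
    """Fraction of window frames in which each residue contacts the ligand.

    ``residues`` may be residue numbers, ResidueIds, or None for every
    non-ligand residue; residues with no sidechain heavy atoms (glycine)
    report 0.  ``window`` is a half-open frame range, default all frames.
    """
    lo, hi = window if window is not None else (0, traj.n_frames)
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError(f"empty or invalid frame window ({lo}, {hi})")
    topo = traj.topology
    lig_idx = _ligand_heavy_indices(topo, ligand)
    universe = _residue_universe(topo, residues, ligand)
    # concatenated sidechain-heavy indices with per-residue segments
    seg_res: list[ResidueId] = []
    seg_start: list[int] = []
    flat: list[int] = []
    for r in universe:
        idx = sidechain_heavy(topo, r.resid, chain=r.chain).indices
        if idx.size == 0:  # e.g. glycine: contact impossible, fraction 0
            continue
        seg_res.append(r)
        seg_start.append(len(flat))
        flat.extend(int(i) for i in idx)
    counts = dict.fromkeys(universe, 0)
    if flat:
        flat_idx = np.array(flat)
        starts = np.array(seg_start)
        for f in range(lo, hi):
            mins = cdist(traj.frames[f][flat_idx], traj.frames[f][lig_idx]).min(axis=1)
            res_min = np.minimum.reduceat(mins, starts)
            for r, m in zip(seg_res, res_min):
                if m <= cutoff:
                    counts[r] += 1
    n = hi - lo
    return ContactProfile({r: counts[r] / n for r in universe},
                          provenance=f"{topo.id} frames [{lo}, {hi})")


def filter_profile(profiles: Sequence[ContactProfile],
                   min_fraction: float = DEFAULT_BINARIZE) -> list[ResidueId]:
    """Residues reaching ``min_fraction`` in at least one of the profiles.

    Mirrors the display rule "contacts for at least 25% of the time in at
    least one of the simulations"; order follows the first profile.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    order: list[ResidueId] = []
    for p in profiles:
        for r in p.fractions:
            if r not in order:
                order.append(r)
    return [r for r in order
            if any(p.fractions.get(r, 0.0) >= min_fraction for p in profiles)]


def fingerprint_matrix(traj: Trajectory, groups: LigandGroupMap,
                       residues: Sequence[int | ResidueId] | None,
                       ligand: Selection,
                       occupancy_threshold: float = DEFAULT_BINARIZE,
                       window: tuple[int, int] | None = None,
                       cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Binary ligand-group x residue fingerprint matrix.

    Entry (g, r) is 1 iff the contact fraction between group g's heavy atoms
    and residue r's sidechain heavy atoms reaches ``occupancy_threshold``.
    Rows are group labels, columns residue labels.
    """
    topo = traj.topology
    lig_names = {topo.atoms[i].name for i in ligand.indices}
    rows = {}
    for gname, names in groups.groups.items():
        missing = sorted(names - lig_names)
        if missing:
            raise KeyError(f"group {gname!r}: atoms {missing} not found in ligand selection")
        gidx = tuple(int(i) for i in ligand.indices
                     if topo.atoms[i].name in names and topo.atoms[i].is_heavy)
        if not gidx:
            raise ValueError(f"group {gname!r} has no heavy atoms")
        gsel = Selection(gidx, label=f"group:{gname}")
        prof = contact_profile(traj, residues, gsel, window=window, cutoff=cutoff)
        rows[gname] = {r.label(): int(f >= occupancy_threshold)
                       for r, f in prof.fractions.items()}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


def tanimoto(a: BinaryProfile, b: BinaryProfile) -> float:
    """Tanimoto coefficient between two binary contact profiles.

    Profiles are aligned on the union of their residues (absent residue = 0).
    Undefined (raises) when both profiles are all-zero.
    """
    union = set(a.values) | set(b.values)
    xa = np.array([a.values.get(r, 0) for r in union], dtype=float)
    xb = np.array([b.values.get(r, 0) for r in union], dtype=float)
    ab = float(xa @ xb)
    denom = float((xa ** 2).sum() + (xb ** 2).sum() - ab)
    if denom == 0.0:
        raise ValueError("Tanimoto undefined: both profiles are all-zero")
    return ab / denom


def tanimoto_matrix(profiles: Mapping[str, BinaryProfile]) -> pd.DataFrame:
    """Symmetric pairwise Tanimoto table over labelled binary profiles."""
    labels = list(profiles)
    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            s = tanimoto(profiles[la], profiles[lb])
            mat.loc[la, lb] = mat.loc[lb, la] = s
    return mat


def crystal_contact_profile(structure: Structure, ligand_resname: str,
                            cutoff: float = DEFAULT_CUTOFF) -> BinaryProfile:
    """Single-structure binary contact profile for a named ligand.

    Applies the same sidechain-heavy contact rule to one frame, e.g. the
    contacts of a co-crystallised ligand in a crystal structure.
    """
    lig_idx = tuple(i for i, a in enumerate(structure.atoms)
                    if a.residue_name.upper() == ligand_resname.upper() and a.is_heavy)
    if not lig_idx:
        raise ValueError(f"ligand {ligand_resname!r} not found in structure")
    lig = Selection(lig_idx, label=f"ligand:{ligand_resname}")
    traj = Trajectory(structure, [structure.coords], frame_interval=1.0)
    prof = contact_profile(traj, None, lig, cutoff=cutoff)
    return BinaryProfile({r: int(f > 0) for r, f in prof.fractions.items()},
                         threshold_used=0.0)
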