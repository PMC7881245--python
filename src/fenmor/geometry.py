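"""Per-frame geometric observables.

Implements the metrics used to characterise ligand binding modes in a GPCR:
minimum inter-selection distances (e.g. piperidine N to the Asp147
carboxylate oxygens), the ligand's vertical position along the membrane
normal (dZ, computed between mass-weighted centers with the flexible terminal
residues excluded from the receptor center), the ligand's vertical tilt
angle, sidechain chi2 dihedrals, and least-squares rigid superposition with
RMSD (the weighted-ensemble progress coordinate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Selection, Structure, Trajectory

__all__ = [
    "min_distance",
    "delta_z",
    "vertical_angle",
    "chi2",
    "dihedral",
    "superpose_rmsd",
    "RigidTransform",
    "com_track",
    "ligand_rmsd_series",
    "pairwise_ligand_rmsd",
    "compute_frame_metrics",
]

#: chi2 defining atoms (IUPAC): N-CA-CB-CG is chi1; chi2 starts at CA
CHI2_ATOMS = {
    "TRP": ("CA", "CB", "CG", "CD1"),
    "PHE": ("CA", "CB", "CG", "CD1"),
    "TYR": ("CA", "CB", "CG", "CD1"),
    "HIS": ("CA", "CB", "CG", "ND1"),
    "ASP": ("CA", "CB", "CG", "OD1"),
}


def _require(sel: Selection, what: str) -> np.ndarray:
    if len(sel) == 0:
        raise ValueError(f"empty selection for {what} ({sel.label!r})")
    return sel.indices


def min_distance(traj: Trajectory, sel_a: Selection, sel_b: Selection) -> np.ndarray:
    """Per-frame minimum pairwise distance between two selections (Angstrom)."""
    ia = _require(sel_a, "min_distance selection A")
    ib = _require(sel_b, "min_distance selection B")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = cdist(traj.frames[f][ia], traj.frames[f][ib]).min()
    return out


def _com(coords: np.ndarray, masses: np.ndarray, mass_weighted: bool) -> np.ndarray:
    if mass_weighted:
        return (coords * masses[:, None]).sum(axis=0) / masses.sum()
    return coords.mean(axis=0)


def delta_z(traj: Trajectory, ligand: Selection, receptor: Selection,
            excluded_resids: Sequence[tuple[int, int]] = ((52, 65), (336, 347)),
            mass_weighted: bool = True, signed: bool = False) -> np.ndarray:
    """Ligand-receptor center-of-mass separation along z (membrane normal).

    Flexible terminal residues (default: N-terminal 52-65 and C-terminal
    336-347) are excluded from the receptor center.  Reported as absolute
    value unless ``signed``.
    """
    il = _require(ligand, "delta_z ligand")
    ir_all = _require(receptor, "delta_z receptor")
    atoms = traj.topology.atoms
    keep = [i for i in ir_all
            if not any(lo <= atoms[i].residue_seq <= hi for lo, hi in excluded_resids)]
    if not keep:
        raise ValueError("excluded residue ranges removed every receptor atom")
    ir = np.array(keep, dtype=int)
    masses = traj.topology.masses
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        zl = _com(traj.frames[f][il], masses[il], mass_weighted)[2]
        zr = _com(traj.frames[f][ir], masses[ir], mass_weighted)[2]
        out[f] = (zl - zr) if signed else abs(zl - zr)
    return out


def vertical_angle(traj: Trajectory, ligand: Selection,
                   collinear_tol: float = 1e-8) -> np.ndarray:
    """Angle between the ligand heavy-atom principal axis and z, in [0, 90] deg.

    The principal axis is the largest-spread eigenvector of the coordinate
    second-moment tensor of the ligand's heavy atoms.  Near-collinear ligands
    still have a well-defined long axis; a warning is emitted because the
    remaining axes are degenerate.
    """
    atoms = traj.topology.atoms
    il = np.array([i for i in _require(ligand, "vertical_angle ligand") if atoms[i].is_heavy])
    if il.size < 2:
        raise ValueError("vertical_angle needs at least 2 heavy atoms")
    out = np.empty(traj.n_frames)
    warned = False
    for f in range(traj.n_frames):
        xyz = traj.frames[f][il]
        centered = xyz - xyz.mean(axis=0)
        cov = centered.T @ centered / len(il)
        evals, evecs = np.linalg.eigh(cov)
        if not warned and evals[1] < collinear_tol * max(evals[2], 1e-30):
            warnings.warn("ligand atoms are (near-)collinear; vertical angle computed "
                          "from the single long axis", stacklevel=2)
            warned = True
        axis = evecs[:, 2]
        cosang = min(1.0, abs(axis[2]) / np.linalg.norm(axis))
        out[f] = np.degrees(np.arccos(cosang))
    return out


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in (-180, 180], IUPAC sign convention."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a fourth point at given bond length, bond angle and torsion.

    Inverse of :func:`dihedral`: ``dihedral(p0, p1, p2, place_dihedral(...))``
    returns ``torsion_deg``.
    """
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = (p2 - p1) / np.linalg.norm(p2 - p1)
    n = np.cross(p1 - p0, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)])
    return p2 + d[0] * bc + d[1] * m + d[2] * n


def chi2(structure: Structure, resid: int, chain: str | None = None) -> float:
    """Sidechain chi2 dihedral (degrees) of one residue.

    Atom quadruples follow the IUPAC convention (Trp/Phe/Tyr: CA-CB-CG-CD1;
    His: CA-CB-CG-ND1; Asp: CA-CB-CG-OD1).
    """
    res_atoms = {a.name.upper(): a for a in structure.atoms
                 if a.residue_seq == resid and (chain is None or a.chain == chain)}
    if not res_atoms:
        raise KeyError(f"residue {resid} not found")
    resname = next(iter(res_atoms.values())).residue_name.upper()
    quad = CHI2_ATOMS.get(resname)
    if quad is None:
        raise KeyError(f"no chi2 atom convention for residue type {resname!r}")
    pts = []
    for name in quad:
        if name not in res_atoms:
            raise KeyError(f"residue {resname}{resid}: missing atom {name!r} for chi2")
        pts.append(res_atoms[name].position)
    return dihedral(*pts)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> R @ x + t``."""

    rotation: np.ndarray   # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation + translation mapping mobile onto reference."""
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return RigidTransform(rot, cr - rot @ cm)


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray,
                   fit_selection: Selection | None = None,
                   rmsd_selection: Selection | None = None) -> tuple[RigidTransform, float]:
    """Rigid superposition of ``mobile`` onto ``reference`` and RMSD.

    The transform is fitted on ``fit_selection`` (all atoms if None) and the
    RMSD is evaluated on ``rmsd_selection`` after applying it.  With the two
    selections equal this is standard fitted RMSD; with fit on receptor
    C-alpha and RMSD on ligand heavy atoms it is the receptor-fit,
    ligand-evaluated progress coordinate used for path sampling.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ifit = fit_selection.indices if fit_selection is not None else np.arange(len(mobile))
    irms = rmsd_selection.indices if rmsd_selection is not None else ifit
    if len(ifit) < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    tr = _kabsch(mobile[ifit], reference[ifit])
    moved = tr.apply(mobile[irms])
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference[irms]) ** 2, axis=1))))
    return tr, rmsd


def com_track(traj: Trajectory, selections: Sequence[Selection],
              origin_selection: Selection, stride_ns: float,
              mass_weighted: bool = True) -> pd.DataFrame:
    """Center-of-mass tracks relative to a reference center, sampled at a stride.

    Returns a tidy table ``(label, frame, time_ns, x, y, z)``; typical use is
    ligand and key-residue positions with the whole receptor center at the
    origin, sampled every 10 ns.
    """
    ratio = stride_ns / traj.frame_interval
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-9:
        near = max(1, int(round(ratio))) * traj.frame_interval
        raise ValueError(f"stride {stride_ns} ns is not a multiple of the frame "
                         f"interval {traj.frame_interval} ns; nearest valid stride is {near} ns")
    io = _require(origin_selection, "com_track origin")
    masses = traj.topology.masses
    rows = []
    for sel in selections:
        isel = _require(sel, "com_track selection")
        for f in range(0, traj.n_frames, step):
            origin = _com(traj.frames[f][io], masses[io], mass_weighted)
            com = _com(traj.frames[f][isel], masses[isel], mass_weighted)
            rel = com - origin
            rows.append((sel.label, f, f * traj.frame_interval, rel[0], rel[1], rel[2]))
    return pd.DataFrame(rows, columns=["label", "frame", "time_ns", "x", "y", "z"])


def ligand_rmsd_series(traj: Trajectory, ligand: Selection,
                       fit_selection: Selection | None = None,
                       reference_frame: int = 0) -> np.ndarray:
    """Ligand heavy-atom RMSD of each frame vs a reference frame.

    Frames are first superposed on ``fit_selection`` (receptor C-alpha by
    convention); with ``fit_selection=None`` the ligand itself is fitted.
    """
    atoms = traj.topology.atoms
    il = np.array([i for i in _require(ligand, "ligand_rmsd ligand") if atoms[i].is_heavy])
    lig_sel = Selection(tuple(int(i) for i in il), label="ligand-heavy")
    ref = traj.frames[reference_frame]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, out[f] = superpose_rmsd(traj.frames[f], ref,
                                   fit_selection=fit_selection or lig_sel,
                                   rmsd_selection=lig_sel)
    return out


def pairwise_ligand_rmsd(traj: Trajectory, ligand: Selection,
                         fit_selection: Selection | None = None) -> np.ndarray:
    """Symmetric (F, F) matrix of ligand heavy-atom RMSD between frames.

    If ``fit_selection`` is given, every frame is first aligned to frame 0 on
    that selection and the ligand RMSD is then computed without further
    fitting (pose differences within the receptor frame).  Without it each
    pair is best-fit on the ligand itself (conformational differences only).
    """
    atoms = traj.topology.atoms
    il = np.array([i for i in _require(ligand, "pairwise_rmsd ligand") if atoms[i].is_heavy])
    n = traj.n_frames
    if fit_selection is not None:
        aligned = np.empty((n, len(il), 3))
        for f in range(n):
            tr, _ = superpose_rmsd(traj.frames[f], traj.frames[0], fit_selection=fit_selection)
            aligned[f] = tr.apply(traj.frames[f][il])
        mat = np.zeros((n, n))
        for i in range(n):
            diff = aligned[i + 1:] - aligned[i]
            if diff.size:
                mat[i, i + 1:] = np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))
        return mat + mat.T
    lig_sel = Selection(tuple(int(i) for i in il))
    mat = np.zeros((n, n))
    sub = traj.frames[:, il, :]
    for i in range(n):
        for j in range(i + 1, n):
            _, mat[i, j] = superpose_rmsd(sub[i], sub[j])
    return mat + mat.T


def compute_frame_metrics(traj: Trajectory, ligand: Selection, receptor: Selection,
                          d147_pair: tuple[Selection, Selection],
                          h297_pair: tuple[Selection, Selection],
                          excluded_resids: Sequence[tuple[int, int]] = ((52, 65), (336, 347)),
                          fit_selection: Selection | None = None) -> pd.DataFrame:
    """Tidy per-frame metric table: distances, dZ, vertical angle, ligand RMSD."""
    df = pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "time_ns": traj.times_ns,
        "d_fen_d147": min_distance(traj, *d147_pair),
        "d_fen_h297": min_distance(traj, *h297_pair),
        "delta_z": delta_z(traj, ligand, receptor, excluded_resids=excluded_resids),
        "vertical_angle": vertical_angle(traj, ligand),
        "ligand_rmsd": ligand_rmsd_series(traj, ligand, fit_selection=fit_selection),
    })
    return df
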