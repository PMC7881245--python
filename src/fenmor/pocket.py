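"""Grid-based binding-site volume with a fixed inclusion region.

Snapshots are first rigidly superposed on the C-alpha atoms of a list of
binding-site residues; a regular grid then tiles a fixed inclusion box
(cells anchored at the box corner, default spacing 1.0 Angstrom), and a grid
point counts as free when it lies outside the van der Waals radius of every
protein heavy atom.  Volume = free points x spacing^3.  Optional probe
radius inflation is available to reconcile settings differences with other
grid-volume tools; no contiguity filtering is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Atom, Selection, Structure, Trajectory
from .geometry import superpose_rmsd

__all__ = [
    "BONDI_VDW_RADII",
    "MOR_BINDING_SITE_RESIDUES",
    "InclusionBox",
    "VolumeResult",
    "align_to_reference",
    "pocket_volume",
    "volume_trajectory",
]

#: van der Waals radii, Angstrom (Bondi 1964 compilation; heavy atoms only
#: are consulted, so H is listed merely for completeness)
BONDI_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "FE": 2.00,
}
_DEFAULT_RADIUS = 1.70

#: 21 orthosteric-site residues of the mu-opioid receptor used for alignment
MOR_BINDING_SITE_RESIDUES = (75, 124, 127, 133, 144, 147, 148, 151, 152, 232,
                             233, 236, 240, 293, 296, 297, 300, 318, 319, 322, 326)


@dataclass(frozen=True)
class InclusionBox:
    """Axis-aligned search region: center and side lengths, Angstrom."""

    center: tuple[float, float, float] = (0.0, 0.0, 8.0)
    sides: tuple[float, float, float] = (12.0, 12.0, 15.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sides):
            raise ValueError("box sides must be positive")

    def grid(self, spacing: float) -> np.ndarray:
        """Cell-center grid tiling the box from its corner."""
        center = np.asarray(self.center, float)
        sides = np.asarray(self.sides, float)
        corner = center - sides / 2.0
        axes = [corner[k] + spacing * (np.arange(int(np.floor(sides[k] / spacing))) + 0.5)
                for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class VolumeResult:
    volume: float            # Angstrom^3
    grid_spacing: float
    n_points_total: int
    n_points_free: int

    def __post_init__(self) -> None:
        expect = self.n_points_free * self.grid_spacing ** 3
        if abs(self.volume - expect) > 1e-6:
            raise ValueError("volume inconsistent with free-point count")


def align_to_reference(structure: Structure, reference: Structure,
                       site_residues: Sequence[int] = MOR_BINDING_SITE_RESIDUES) -> Structure:
    """Rigidly superpose a structure onto a reference using site C-alpha atoms."""
    def ca_map(st: Structure) -> dict[int, int]:
        return {a.residue_seq: i for i, a in enumerate(st.atoms) if a.name.upper() == "CA"}

    mob_ca, ref_ca = ca_map(structure), ca_map(reference)
    missing = [r for r in site_residues if r not in mob_ca or r not in ref_ca]
    if missing:
        raise KeyError(f"missing C-alpha for binding-site residue(s) {missing}")
    mob_idx = np.array([mob_ca[r] for r in site_residues])
    ref_idx = np.array([ref_ca[r] for r in site_residues])
    tr, _ = superpose_rmsd(structure.coords[mob_idx], reference.coords[ref_idx])
    return structure.with_coords(tr.apply(structure.coords), id=f"{structure.id}|aligned")


def _strip(structure: Structure, strip_resnames: Sequence[str] | None) -> list[Atom]:
    drop = {s.upper() for s in (strip_resnames or ())}
    return [a for a in structure.atoms if a.residue_name.upper() not in drop]


def pocket_volume(structure: Structure, box: InclusionBox = InclusionBox(),
                  spacing: float = 1.0, strip_resnames: Sequence[str] | None = None,
                  probe_radius: float = 0.0) -> VolumeResult:
    """Free volume of the inclusion box around the given (aligned) structure.

    ``strip_resnames`` removes waters/ions/ligands etc. before the
    calculation; remaining heavy atoms occlude grid points within their van
    der Waals radius (+ ``probe_radius``).
    """
    if spacing <= 0 or spacing > min(box.sides):
        raise ValueError(f"grid spacing {spacing} must be in (0, {min(box.sides)}]")
    atoms = [a for a in _strip(structure, strip_resnames) if a.is_heavy]
    points = box.grid(spacing)
    if not atoms:
        free = points.shape[0]
        return VolumeResult(free * spacing ** 3, spacing, points.shape[0], free)
    coords = np.array([a.position for a in atoms])
    radii = np.array([BONDI_VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS)
                      for a in atoms]) + probe_radius
    # prune atoms too far from the box to matter
    center = np.asarray(box.center)
    half = np.asarray(box.sides) / 2.0
    margin = radii.max()
    near = np.all(np.abs(coords - center) <= half + margin, axis=1)
    coords, radii = coords[near], radii[near]
    occupied = np.zeros(points.shape[0], dtype=bool)
    if coords.size:
        tree = cKDTree(points)
        for xyz, r in zip(coords, radii):
            occupied[tree.query_ball_point(xyz, r)] = True
    free = int((~occupied).sum())
    return VolumeResult(free * spacing ** 3, spacing, points.shape[0], free)


def volume_trajectory(traj: Trajectory, reference: Structure,
                      box: InclusionBox = InclusionBox(), every_ns: float = 5.0,
                      window_ns: float = 50.0, spacing: float = 1.0,
                      site_residues: Sequence[int] = MOR_BINDING_SITE_RESIDUES,
                      strip_resnames: Sequence[str] | None = None,
                      probe_radius: float = 0.0) -> tuple[list[VolumeResult], float, float]:
    """Volume over trajectory snapshots: align each sampled frame, grid it.

    Snapshots are taken every ``every_ns`` from the last ``window_ns`` of the
    trajectory.  Returns (per-snapshot results, mean, sd).
    """
    total_ns = traj.n_frames * traj.frame_interval
    if window_ns > total_ns:
        raise ValueError(f"window {window_ns} ns longer than trajectory ({total_ns} ns)")
    step = max(1, int(round(every_ns / traj.frame_interval)))
    start = traj.n_frames - int(round(window_ns / traj.frame_interval))
    results = []
    for f in range(start, traj.n_frames, step):
        frame = traj.frame_structure(f)
        aligned = align_to_reference(frame, reference, site_residues)
        results.append(pocket_volume(aligned, box, spacing=spacing,
                                     strip_resnames=strip_resnames,
                                     probe_radius=probe_radius))
    vols = np.array([r.volume for r in results])
    return results, float(vols.mean()), float(vols.std(ddof=1) if len(vols) > 1 else 0.0)
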