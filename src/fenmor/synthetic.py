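"""Synthetic fixtures with known ground truth.

Builds a stylised receptor-ligand complex that reproduces, at toy scale, the
geometry of the two fentanyl binding modes in the mu-opioid receptor: a
salt-bridge site (Asp-like carboxylate, "D147") and a hydrogen-bond site
(His-like N-epsilon, "H297") placed 120 degrees around the pocket axis,
2 Angstrom away laterally and 1 Angstrom deeper, which is the displacement
separating the two modes.  Trajectories switch modes through a Markov chain
with prescribed stationary occupancies and add isotropic Gaussian noise to
the ligand; titration series draw per-frame protonation states from
Henderson-Hasselbalch probabilities with a prescribed pKa, Hill coefficient
and tautomer bias, optionally coupled to a paired ligand-residue distance
(HID forced whenever the distance is under 4 Angstrom).

These are statistical emulations for validating the analysis layer, not
physical models: there is no force field, no excluded volume and no
receptor flexibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import Atom, LigandGroupMap, Selection, Structure, Trajectory, select
from .titration import HIS_STATES, TWO_STATES, TitrationSeries

__all__ = [
    "ModePlacement",
    "ToyComplexSpec",
    "ToyComplex",
    "make_toy_complex",
    "simulate_mode_trajectory",
    "TitrationSpec",
    "simulate_titration",
    "make_coupled_distances",
    "make_state_conditional_distances",
    "STATE_DISTANCE_PARAMS",
    "APO_HIS297",
    "D147_HIS297",
    "H297_HIS297",
    "APO_ASP114",
]

MODE_NAMES = ("D147", "H297", "UNBOUND")

# ---------------------------------------------------------------------------
# Ligand template (local frame; heavy atoms of a stylised 4-anilidopiperidine)
# ---------------------------------------------------------------------------

_LIGAND_ATOMS: list[tuple[str, str, tuple[float, float, float]]] = [
    # piperidine ring, amine nitrogen at the origin
    ("N1", "N", (0.00, 0.00, 0.00)),
    ("C2", "C", (1.25, 0.60, 0.40)),
    ("C3", "C", (1.20, 2.00, 0.80)),
    ("C4", "C", (0.00, 2.70, 0.60)),
    ("C5", "C", (-1.20, 2.00, 0.80)),
    ("C6", "C", (-1.25, 0.60, 0.40)),
    # phenethyl arm, extending along the long axis
    ("C7", "C", (0.30, -0.80, 1.10)),
    ("C8", "C", (0.30, -1.20, 2.50)),
    ("C9", "C", (0.30, -1.40, 3.90)),
    ("C10", "C", (1.40, -1.70, 4.70)),
    ("C11", "C", (1.40, -1.80, 6.10)),
    ("C12", "C", (0.30, -1.60, 6.80)),
    ("C13", "C", (-0.80, -1.30, 6.10)),
    ("C14", "C", (-0.80, -1.20, 4.70)),
    # propanamide branch
    ("N2", "N", (0.20, 3.30, -0.60)),
    ("C15", "C", (1.30, 3.80, -1.20)),
    ("O1", "O", (2.30, 3.30, -1.00)),
    ("C16", "C", (1.20, 5.00, -2.10)),
    ("C17", "C", (2.40, 5.50, -2.80)),
    # anilino phenyl ring
    ("C18", "C", (-0.90, 3.90, -1.30)),
    ("C19", "C", (-1.10, 5.00, -2.10)),
    ("C20", "C", (-2.30, 5.40, -2.60)),
    ("C21", "C", (-3.40, 4.70, -2.30)),
    ("C22", "C", (-3.20, 3.60, -1.50)),
    ("C23", "C", (-2.00, 3.20, -1.00)),
]

_LIGAND_GROUPS = {
    "piperidine": ["N1", "C2", "C3", "C4", "C5", "C6"],
    "phenethyl": ["C7", "C8", "C9", "C10", "C11", "C12", "C13", "C14"],
    "propanamide": ["N2", "C15", "O1", "C16", "C17"],
    "phenyl": ["C18", "C19", "C20", "C21", "C22", "C23"],
}

LIGAND_RESNAME = "FEN"
LIGAND_RESID = 900
LIGAND_CHAIN = "L"


def _rot_z(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _canonical_ligand() -> np.ndarray:
    """Template coords with amine at origin and principal axis along +z."""
    xyz = np.array([p for _, _, p in _LIGAND_ATOMS], dtype=float)
    xyz -= xyz[0]  # amine at origin
    centered = xyz - xyz.mean(axis=0)
    _, evecs = np.linalg.eigh(centered.T @ centered)
    axis = evecs[:, 2]
    com = xyz.mean(axis=0)
    if com @ axis < 0:
        axis = -axis
    # rotation taking the principal axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    out = xyz @ rot.T
    return out - out[0]


@dataclass(frozen=True)
class ModePlacement:
    """Ligand placement for one mode: tilt from vertical (deg), lateral
    rotation about z (deg), and the anchor point where the amine N sits."""

    tilt_deg: float
    zrot_deg: float
    anchor: tuple[float, float, float]

    def place(self, canonical: np.ndarray) -> np.ndarray:
        r = np.radians(self.tilt_deg)
        c, s = np.cos(r), np.sin(r)
        ry = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        rot = _rot_z(self.zrot_deg) @ ry
        placed = canonical @ rot.T
        return placed + (np.asarray(self.anchor) - placed[0])


_ANCHOR_D = (4.0, 0.0, 6.2)
# 120 deg around the pocket, 2 A lateral, 1 A deeper: the D147 -> H297 move
_ANCHOR_H = (4.0 - 1.0, np.sqrt(3.0), 6.2 - 1.0)

DEFAULT_MODE_TEMPLATES: dict[str, ModePlacement] = {
    "D147": ModePlacement(30.0, 0.0, _ANCHOR_D),
    "H297": ModePlacement(15.0, 120.0, _ANCHOR_H),
    "UNBOUND": ModePlacement(40.0, 60.0, (7.0, -3.0, 12.5)),
}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Conditions for the two-mode synthetic trajectory.

    Defaults: mode occupancies 0.7 / 0.2 / 0.1 (D147 / H297 / unbound),
    Markov stay-probability 0.9, isotropic ligand positional noise of
    0.2 Angstrom, 1 ns between frames.
    """

    noise_sd: float = 0.2
    occupancies: tuple[float, float, float] = (0.7, 0.2, 0.1)
    stickiness: float = 0.9
    transition_matrix: tuple[tuple[float, ...], ...] | None = None
    n_frames: int = 2000
    frame_interval: float = 1.0
    seed: int = 0
    mode_templates: Mapping[str, ModePlacement] = field(
        default_factory=lambda: dict(DEFAULT_MODE_TEMPLATES))
    delta_z_d147: float = 8.4   # target ligand-receptor z separation, D147 mode

    def resolved_transition_matrix(self) -> np.ndarray:
        pi = np.asarray(self.occupancies, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
            raise ValueError("occupancies must be non-negative and sum to 1")
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            if t.shape != (3, 3) or not np.allclose(t.sum(axis=1), 1.0):
                raise ValueError("transition matrix must be 3x3 row-stochastic")
            return t
        s = self.stickiness
        return s * np.eye(3) + (1.0 - s) * np.tile(pi, (3, 1))


@dataclass
class ToyComplex:
    """A built toy complex: structure (ligand placed in the start template),
    substituent map, per-mode ligand templates, and canonical selections."""

    structure: Structure
    groups: LigandGroupMap
    mode_coords: dict[str, np.ndarray]   # mode -> ligand coords (n_lig, 3)
    ligand_index: np.ndarray             # indices of ligand atoms in structure

    def ligand_selection(self) -> Selection:
        return Selection(tuple(int(i) for i in self.ligand_index), label="ligand")

    def receptor_selection(self) -> Selection:
        lig = set(self.ligand_index.tolist())
        return Selection(tuple(i for i in range(len(self.structure)) if i not in lig),
                         label="receptor")

    def amine_selection(self) -> Selection:
        return select(self.structure, f"resname {LIGAND_RESNAME} and name N1", label="amine-N")

    def carboxylate_selection(self) -> Selection:
        return select(self.structure, "resid 147 and name OD1 OD2", label="D147-carboxylate")

    def ne2_selection(self) -> Selection:
        return select(self.structure, "resid 297 and name NE2", label="H297-NE2")

    def receptor_ca_selection(self) -> Selection:
        idx = tuple(i for i, a in enumerate(self.structure.atoms)
                    if a.name == "CA" and i not in set(self.ligand_index.tolist()))
        return Selection(idx, label="receptor-CA")


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _backbone(center: np.ndarray, away: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    u = _unit(away)
    perp = _unit(np.cross(u, [0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.cross(u, [1.0, 0.0, 0.0]))
    return [
        ("CA", "C", center),
        ("N", "N", center + 1.45 * perp),
        ("C", "C", center - 1.5 * perp + 0.3 * u),
        ("O", "O", center - 1.9 * perp + 1.3 * u),
    ]


def _receptor_atoms(mode_coords: Mapping[str, np.ndarray],
                    lig_names: Sequence[str]) -> list[Atom]:
    """Construct the pseudo-receptor around the placed ligand templates."""
    name_idx = {n: i for i, n in enumerate(lig_names)}
    d_pose, h_pose = mode_coords["D147"], mode_coords["H297"]
    anchor_d, anchor_h = d_pose[name_idx["N1"]], h_pose[name_idx["N1"]]
    pocket_center = (anchor_d + anchor_h) / 2.0

    atoms: list[Atom] = []

    def add(resname: str, resid: int, parts: Sequence[tuple[str, str, np.ndarray]]):
        for name, el, xyz in parts:
            atoms.append(Atom(name, el, resid, resname, "A", np.asarray(xyz, float)))

    # --- Asp147: carboxylate pointing away from the His site
    dir_d = _unit(np.append(_unit((anchor_d - anchor_h)[:2]), -0.3))
    od1 = anchor_d + 2.7 * dir_d
    perp_d = _unit(np.cross(dir_d, [0.0, 0.0, 1.0]))
    od2 = anchor_d + 2.7 * dir_d + 2.2 * _unit(perp_d - [0, 0, 0.4])
    cg = anchor_d + 3.9 * dir_d
    cb = anchor_d + 5.3 * dir_d
    add("ASP", 147, [("OD1", "O", od1), ("OD2", "O", od2), ("CG", "C", cg), ("CB", "C", cb)]
        + _backbone(anchor_d + 6.8 * dir_d, dir_d))

    # --- His297: imidazole N-epsilon pointing away from the Asp site
    dir_h = _unit(np.append(_unit((anchor_h - anchor_d)[:2]), -0.3))
    ne2 = anchor_h + 2.8 * dir_h
    perp_h = _unit(np.cross(dir_h, [0.0, 0.0, 1.0]))
    ce1 = ne2 + 1.35 * _unit(dir_h + 0.8 * perp_h)
    nd1 = ne2 + 2.2 * _unit(dir_h + 0.35 * perp_h)
    cd2 = ne2 + 1.35 * _unit(dir_h - 0.8 * perp_h)
    cg_h = ne2 + 2.2 * _unit(dir_h - 0.35 * perp_h)
    cb_h = ne2 + 3.6 * dir_h
    add("HIS", 297, [("NE2", "N", ne2), ("CE1", "C", ce1), ("ND1", "N", nd1),
                     ("CD2", "C", cd2), ("CG", "C", cg_h), ("CB", "C", cb_h)]
        + _backbone(anchor_h + 7.0 * dir_h, dir_h))

    # --- satellite pocket residues: single sidechain tips placed near chosen
    # ligand template atoms so the two modes leave distinct contact sets
    def near(pose: np.ndarray, atom: str, dist: float = 3.4) -> np.ndarray:
        p = pose[name_idx[atom]]
        away = _unit(np.append(_unit((p - pocket_center)[:2] + 1e-9), 0.1))
        return p + dist * away

    satellites = [
        ("GLN", 124, "NE2", "N", near(d_pose, "C20")),
        ("TRP", 133, "CZ2", "C", near(d_pose, "C17")),
        ("MET", 151, "SD", "S", near(d_pose, "C12", 3.6)),
        ("ILE", 296, "CD1", "C", near(h_pose, "C14")),
        ("VAL", 300, "CG1", "C", near(h_pose, "C5")),
        ("TRP", 318, "CH2", "C", near(d_pose, "C3")),
        ("ILE", 322, "CD1", "C", (near(d_pose, "C8") + near(h_pose, "C8")) / 2.0),
        ("TYR", 326, "OH", "O", (near(d_pose, "C6") + near(h_pose, "C6")) / 2.0),
        ("ASP", 114, "OD1", "O", pocket_center + np.array([0.0, 0.5, -4.5])),
    ]
    for resname, resid, name, el, xyz in satellites:
        away = _unit(np.append(_unit((xyz - pocket_center)[:2] + 1e-9), 0.0))
        add(resname, resid, [(name, el, xyz)] + _backbone(xyz + 3.5 * away, away))

    # --- Trp293: chi2-defining quadruple below the pocket (phenethyl stack);
    # CD1 placed at chi2 = +120 degrees, the active-state rotamer
    from .geometry import place_dihedral
    ca = pocket_center + np.array([-3.0, -4.5, -2.0])
    cb293 = ca + np.array([1.0, 1.0, 0.5])
    cg293 = cb293 + np.array([0.6, 1.2, 0.3])
    cd1 = place_dihedral(ca, cb293, cg293, 1.4, 127.0, 120.0)
    parts = [("CB", "C", cb293), ("CG", "C", cg293), ("CD1", "C", cd1)]
    bb = _backbone(ca, np.array([-1.0, -1.0, 0.0]))
    add("TRP", 293, [p for p in parts] + [p for p in bb if p[0] != "CA"]
        + [("CA", "C", ca)])

    # --- bulk helical ring, symmetric in z (receptor core center definition)
    for k in range(16):
        ang = 2 * np.pi * k / 16
        zz = 6.0 if k % 2 == 0 else -6.0
        c = np.array([12.0 * np.cos(ang), 12.0 * np.sin(ang), zz])
        add("ALA", 180 + k, [("CB", "C", c + np.array([0.0, 0.0, 1.0]))]
            + _backbone(c, c / np.linalg.norm(c)))

    # --- flexible terminal residues, excluded from the receptor core center
    for k, resid in enumerate(range(52, 66)):        # N-terminal tail, high z
        ang = 2 * np.pi * k / 14
        c = np.array([6.0 * np.cos(ang), 6.0 * np.sin(ang), 15.5 + 0.4 * k])
        add("GLY", resid, _backbone(c, np.array([np.cos(ang), np.sin(ang), 0.2])))
    for k, resid in enumerate(range(336, 348)):      # C-terminal tail, low z
        ang = 2 * np.pi * k / 12
        c = np.array([6.0 * np.cos(ang), 6.0 * np.sin(ang), -15.5 - 0.4 * k])
        add("GLY", resid, _backbone(c, np.array([np.cos(ang), np.sin(ang), -0.2])))

    return atoms


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> ToyComplex:
    """Build the toy receptor-ligand complex and validate its templates.

    The bulk receptor ring is shifted along z so that the D147-mode ligand
    sits ``spec.delta_z_d147`` above the receptor-core center of mass (the
    H297 mode then sits ~1 Angstrom lower, per its template).
    """
    canonical = _canonical_ligand()
    mode_coords = {m: pl.place(canonical) for m, pl in spec.mode_templates.items()}
    for m in MODE_NAMES:
        if m not in mode_coords:
            raise ValueError(f"mode template {m!r} missing")
    lig_names = [n for n, _, _ in _LIGAND_ATOMS]

    rec_atoms = _receptor_atoms(mode_coords, lig_names)

    # calibrate the receptor-core center: shift the bulk ring along z
    masses = np.array([a.mass for a in rec_atoms])
    zs = np.array([a.position[2] for a in rec_atoms])
    core = np.array([not (52 <= a.residue_seq <= 65 or 336 <= a.residue_seq <= 347)
                     for a in rec_atoms])
    bulk = np.array([180 <= a.residue_seq <= 195 for a in rec_atoms])
    lig_elements = [el for _, el, _ in _LIGAND_ATOMS]
    import gemmi as _gemmi
    lig_masses = np.array([_gemmi.Element(e).weight for e in lig_elements])
    lig_com_z = float((mode_coords["D147"][:, 2] * lig_masses).sum() / lig_masses.sum())
    target = lig_com_z - spec.delta_z_d147
    m_core, m_bulk = masses[core].sum(), masses[bulk].sum()
    current = float((zs[core] * masses[core]).sum() / m_core)
    shift = (target - current) * m_core / m_bulk
    rec_atoms = [
        Atom(a.name, a.element, a.residue_seq, a.residue_name, a.chain,
             a.position + np.array([0.0, 0.0, shift]) * (180 <= a.residue_seq <= 195))
        for a in rec_atoms
    ]

    lig_atoms = [Atom(n, el, LIGAND_RESID, LIGAND_RESNAME, LIGAND_CHAIN, xyz)
                 for (n, el, _), xyz in zip(_LIGAND_ATOMS, mode_coords["D147"])]
    structure = Structure(rec_atoms + lig_atoms, id="toy-complex")
    lig_index = np.arange(len(rec_atoms), len(rec_atoms) + len(lig_atoms))
    groups = LigandGroupMap(_LIGAND_GROUPS, amine_atom="N1")
    toy = ToyComplex(structure, groups, mode_coords, lig_index)
    _validate_templates(toy, lig_names)
    return toy


def _validate_templates(toy: ToyComplex, lig_names: Sequence[str]) -> None:
    idx = {n: i for i, n in enumerate(lig_names)}
    od = np.array([a.position for a in toy.structure.atoms
                   if a.residue_seq == 147 and a.name in ("OD1", "OD2")])
    ne2 = np.array([a.position for a in toy.structure.atoms
                    if a.residue_seq == 297 and a.name == "NE2"])

    def d(mode: str, site: np.ndarray) -> float:
        n1 = toy.mode_coords[mode][idx["N1"]]
        return float(np.linalg.norm(site - n1, axis=1).min())

    checks = {
        "D147 amine-carboxylate": (d("D147", od), "le", 3.5),
        "D147 amine-NE2": (d("D147", ne2), "gt", 3.5),
        "H297 amine-NE2": (d("H297", ne2), "le", 3.5),
        "H297 amine-carboxylate": (d("H297", od), "gt", 3.5),
        "UNBOUND amine-carboxylate": (d("UNBOUND", od), "gt", 3.5),
        "UNBOUND amine-NE2": (d("UNBOUND", ne2), "gt", 3.5),
    }
    for what, (val, op, lim) in checks.items():
        ok = val <= lim if op == "le" else val > lim
        if not ok:
            raise ValueError(f"template violates defining distance: {what} = {val:.2f} A "
                             f"(should be {'<=' if op == 'le' else '>'} {lim} A)")
    dz_drop = (toy.mode_coords["D147"].mean(axis=0)[2]
               - toy.mode_coords["H297"].mean(axis=0)[2])
    if not 0.5 <= dz_drop <= 1.5:
        raise ValueError(f"H297 template should sit ~1 A below D147, got {dz_drop:.2f} A")


def simulate_mode_trajectory(spec: ToyComplexSpec = ToyComplexSpec()
                             ) -> tuple[Trajectory, list[str], ToyComplex]:
    """Markov-switching two-mode trajectory with Gaussian ligand noise.

    Returns the trajectory, the ground-truth per-frame mode labels
    (D147 / H297 / UNBOUND), and the underlying toy complex.
    """
    toy = make_toy_complex(spec)
    rng = np.random.default_rng(spec.seed)
    t = spec.resolved_transition_matrix()
    pi = np.asarray(spec.occupancies, dtype=float)
    states = np.empty(spec.n_frames, dtype=int)
    states[0] = rng.choice(3, p=pi)
    for f in range(1, spec.n_frames):
        states[f] = rng.choice(3, p=t[states[f - 1]])
    labels = [MODE_NAMES[s] for s in states]

    base = toy.structure.coords
    frames = np.repeat(base[None], spec.n_frames, axis=0)
    for f, mode in enumerate(labels):
        lig = toy.mode_coords[mode]
        frames[f, toy.ligand_index] = lig + rng.normal(0.0, spec.noise_sd, lig.shape)
    traj = Trajectory(toy.structure, frames, frame_interval=spec.frame_interval)

    # defining-distance violation rate under noise
    idx_n1 = int(toy.ligand_index[0])  # N1 is the first ligand atom
    od = np.array([a.position for a in toy.structure.atoms
                   if a.residue_seq == 147 and a.name in ("OD1", "OD2")])
    ne2 = np.array([a.position for a in toy.structure.atoms
                    if a.residue_seq == 297 and a.name == "NE2"])
    viol = 0
    for f, mode in enumerate(labels):
        n1 = frames[f, idx_n1]
        if mode == "D147" and np.linalg.norm(od - n1, axis=1).min() > 3.5:
            viol += 1
        elif mode == "H297" and np.linalg.norm(ne2 - n1, axis=1).min() > 3.5:
            viol += 1
    rate = viol / spec.n_frames
    if rate > 0.01:
        warnings.warn(f"noise_sd {spec.noise_sd} violates defining distances in "
                      f"{100 * rate:.1f}% of frames", stacklevel=2)
    return traj, labels, toy


# ---------------------------------------------------------------------------
# Titration series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationSpec:
    """Generator conditions for one titratable site across the pH ladder.

    The default ladder is the 16-replica 2.5-9.5 / 0.5 grid.  ``site`` is
    "HIS" (HID/HIE/HIP alphabet) or "ACID" (PROT/DEPROT).  ``tautomer_bias``
    is P(HID | neutral); with ``coupling`` on, frames whose paired distance
    is below ``coupling_cutoff`` sample HID exclusively.
    """

    pka: float = 6.8
    hill_n: float = 1.0
    tautomer_bias: float = 0.5
    site: str = "HIS"
    coupling: bool = False
    coupling_cutoff: float = 4.0
    ph_grid: tuple[float, ...] = tuple(np.arange(2.5, 9.51, 0.5).round(2))
    frames_per_ph: int = 1000
    seed: int = 0
    residue: str = "HIS297"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tautomer_bias <= 1.0:
            raise ValueError("tautomer_bias must be in [0, 1]")
        if list(self.ph_grid) != sorted(self.ph_grid):
            raise ValueError("ph_grid must be ordered")
        if self.site not in ("HIS", "ACID"):
            raise ValueError("site must be 'HIS' or 'ACID'")


# presets reproducing the reported occupancy structure of His297 / Asp114:
# (pKa, Hill slope and tautomer bias chosen to match the published
#  physiological-pH state populations)
APO_HIS297 = TitrationSpec(pka=6.8, hill_n=0.834, tautomer_bias=0.158, residue="HIS297-apo")
D147_HIS297 = TitrationSpec(pka=7.3, hill_n=1.047, tautomer_bias=0.304, residue="HIS297-D147")
H297_HIS297 = TitrationSpec(pka=6.7, hill_n=0.860, tautomer_bias=0.750,
                            coupling=True, residue="HIS297-H297")
APO_ASP114 = TitrationSpec(pka=4.8, hill_n=1.0, site="ACID", residue="ASP114-apo")


def make_coupled_distances(n: int, p_near: float, rng: np.random.Generator,
                           near: tuple[float, float] = (3.0, 0.22),
                           far: tuple[float, float] = (7.4, 0.72)) -> np.ndarray:
    """Bimodal amine-N(epsilon) distances: hydrogen-bonded vs dissociated."""
    is_near = rng.random(n) < p_near
    d = np.where(is_near, rng.normal(*near, n), rng.normal(*far, n))
    return np.maximum(d, 1.5)


#: characteristic amine-N(epsilon) distance (mean, sd) per His state in the
#: hydrogen-bonded binding mode: HID is the H-bonded species, HIE/HIP dissociate
STATE_DISTANCE_PARAMS = {"HID": (3.0, 0.22), "HIE": (7.4, 0.72), "HIP": (8.0, 0.5)}


def make_state_conditional_distances(states: np.ndarray, rng: np.random.Generator,
                                     params: Mapping[str, tuple[float, float]] = None
                                     ) -> np.ndarray:
    """Distances drawn from a per-state Gaussian, paired frame-wise with states."""
    params = dict(STATE_DISTANCE_PARAMS if params is None else params)
    out = np.empty(len(states))
    for s, (mu, sd) in params.items():
        mask = np.asarray(states) == s
        out[mask] = rng.normal(mu, sd, int(mask.sum()))
    return np.maximum(out, 1.5)


def simulate_titration(spec: TitrationSpec = TitrationSpec(),
                       distances: Mapping[float, np.ndarray] | None = None) -> TitrationSeries:
    """Draw per-frame protonation/tautomer states across the pH ladder.

    P(protonated) follows the generalised Henderson-Hasselbalch form at each
    pH; neutral histidine frames choose HID with probability
    ``tautomer_bias`` (forced to HID under the distance-coupling rule).
    """
    rng = np.random.default_rng(spec.seed)
    states: dict[float, np.ndarray] = {}
    dist_out: dict[float, np.ndarray] | None = {} if distances is not None else None
    for ph in spec.ph_grid:
        n = spec.frames_per_ph
        p_prot = 1.0 / (1.0 + 10.0 ** (spec.hill_n * (ph - spec.pka)))
        prot = rng.random(n) < p_prot
        if spec.site == "ACID":
            states[ph] = np.where(prot, "PROT", "DEPROT")
        else:
            if distances is not None:
                d = np.asarray(distances[ph], dtype=float)
                if d.shape != (n,):
                    raise ValueError(f"pH {ph}: distance series length {d.shape[0]} != "
                                     f"frames_per_ph {n}")
            else:
                d = None
            p_hid = np.full(n, spec.tautomer_bias)
            if spec.coupling and d is not None:
                p_hid = np.where(d < spec.coupling_cutoff, 1.0, p_hid)
            hid = rng.random(n) < p_hid
            states[ph] = np.where(prot, "HIP", np.where(hid, "HID", "HIE"))
            if dist_out is not None:
                dist_out[ph] = d
    alphabet = HIS_STATES if spec.site == "HIS" else TWO_STATES
    return TitrationSeries(spec.ph_grid, states, residue=spec.residue,
                           alphabet=alphabet, distances=dist_out)
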