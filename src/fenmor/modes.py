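"""Binding-mode classification, group partitions, and pose clustering.

A frame is D147-bound when the ligand amine-carboxylate distance is within
3.5 Angstrom (salt bridge) and H297-bound when the amine-N(epsilon) distance
is within 3.5 Angstrom (hydrogen bond).  The classifier is total: BOTH and
NEITHER labels cover the remaining cases.  Pose clustering is hierarchical
agglomerative clustering on the pairwise ligand heavy-atom RMSD matrix with a
3 Angstrom distance cutoff, with a medoid-style representative per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .core import Selection, Trajectory
from .geometry import pairwise_ligand_rmsd

logger = logging.getLogger(__name__)

__all__ = [
    "ModeLabel",
    "assign_modes",
    "GroupPredicate",
    "GroupPartition",
    "WE_HIE_GROUPS",
    "WE_HID_GROUPS",
    "partition_groups",
    "PoseClustering",
    "cluster_poses",
]

MODE_THRESHOLD = 3.5  # Angstrom


class ModeLabel(str, Enum):
    D147 = "D147"
    H297 = "H297"
    BOTH = "BOTH"
    NEITHER = "NEITHER"


def assign_modes(d_fen_d147: np.ndarray, d_fen_h297: np.ndarray,
                 threshold: float = MODE_THRESHOLD) -> list[ModeLabel]:
    """Per-frame binding-mode label from the two anchor distances."""
    d1 = np.asarray(d_fen_d147, dtype=float)
    d2 = np.asarray(d_fen_h297, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("distance series must have equal length")
    out = []
    for a, b in zip(d1, d2):
        if a <= threshold and b <= threshold:
            out.append(ModeLabel.BOTH)
        elif a <= threshold:
            out.append(ModeLabel.D147)
        elif b <= threshold:
            out.append(ModeLabel.H297)
        else:
            out.append(ModeLabel.NEITHER)
    return out


@dataclass(frozen=True)
class GroupPredicate:
    """One named predicate over (d_fen_d147, d_fen_h297), with Angstrom bounds."""

    label: str
    test: Callable[[float, float], bool]


@dataclass(frozen=True)
class GroupPartition:
    """Ordered predicate list; first match wins, frames may stay unassigned."""

    name: str
    predicates: tuple[GroupPredicate, ...]


#: group definitions used to post-process the two path-sampling runs
WE_HIE_GROUPS = GroupPartition("WE-HIE", (
    GroupPredicate("group1: d147<=3.5", lambda d1, d2: d1 <= 3.5),
    GroupPredicate("group2: d147>=4 and h297<=8", lambda d1, d2: d1 >= 4.0 and d2 <= 8.0),
    GroupPredicate("group3: d147>=4 and h297>=8", lambda d1, d2: d1 >= 4.0 and d2 >= 8.0),
))

WE_HID_GROUPS = GroupPartition("WE-HID", (
    GroupPredicate("group1: d147<=3.5", lambda d1, d2: d1 <= 3.5),
    GroupPredicate("group2: h297<=3.5", lambda d1, d2: d2 <= 3.5),
    GroupPredicate("group3: d147>=8.5 and h297>=4", lambda d1, d2: d1 >= 8.5 and d2 >= 4.0),
))


def partition_groups(d_fen_d147: np.ndarray, d_fen_h297: np.ndarray,
                     spec: GroupPartition) -> tuple[list[str | None], pd.DataFrame]:
    """Assign frames to the partition's groups (first match wins).

    Returns per-frame group labels (None = unassigned) and an occupancy table
    (group, n_frames, fraction).  Overlapping matches are counted and logged.
    """
    d1 = np.asarray(d_fen_d147, dtype=float)
    d2 = np.asarray(d_fen_h297, dtype=float)
    labels: list[str | None] = []
    overlap = 0
    for a, b in zip(d1, d2):
        hits = [p.label for p in spec.predicates if p.test(a, b)]
        if len(hits) > 1:
            overlap += 1
        labels.append(hits[0] if hits else None)
    if overlap:
        logger.info("%s: %d frame(s) matched more than one predicate (first match kept)",
                    spec.name, overlap)
    n = len(labels)
    rows = []
    for p in spec.predicates:
        c = sum(1 for l in labels if l == p.label)
        rows.append((p.label, c, c / n if n else 0.0))
    return labels, pd.DataFrame(rows, columns=["group", "n_frames", "fraction"])


@dataclass
class PoseClustering:
    """Result of hierarchical pose clustering.

    ``labels`` are 0-based cluster ids ordered by descending cluster size;
    ``representatives`` maps cluster id to the member frame minimising the
    mean RMSD to its cluster (ties broken toward the lowest frame index).
    """

    labels: np.ndarray
    linkage: str
    cutoff: float
    representatives: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


def cluster_poses(traj: Trajectory, ligand: Selection, cutoff: float = 3.0,
                  linkage: str = "average",
                  align_selection: Selection | None = None) -> PoseClustering:
    """Agglomerative pose clustering on the ligand heavy-atom RMSD matrix.

    Frames are pre-aligned on ``align_selection`` (receptor C-alpha by
    convention; None disables pre-alignment and best-fits each pair on the
    ligand).  The dendrogram is cut at the RMSD ``cutoff``.
    """
    if traj.n_frames < 2:
        import warnings
        warnings.warn("single-frame trajectory: one singleton cluster", stacklevel=2)
        return PoseClustering(np.zeros(1, dtype=int), linkage, cutoff, {0: 0})
    mat = pairwise_ligand_rmsd(traj, ligand, fit_selection=align_selection)
    z = scipy_linkage(squareform(mat, checks=False), method=linkage)
    raw = fcluster(z, t=cutoff, criterion="distance")  # 1-based
    # relabel clusters by descending size; ties by lowest member frame
    sizes = {c: int((raw == c).sum()) for c in np.unique(raw)}
    order = sorted(sizes, key=lambda c: (-sizes[c], int(np.nonzero(raw == c)[0][0])))
    remap = {c: i for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    reps: dict[int, int] = {}
    for c in range(len(order)):
        m = np.nonzero(labels == c)[0]
        mean_rmsd = mat[np.ix_(m, m)].mean(axis=1)
        reps[c] = int(m[int(np.argmin(mean_rmsd))])  # argmin takes first on ties
    return PoseClustering(labels, linkage, cutoff, reps)
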