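"""Grid-based binding-site volume inside a fixed inclusion box.

Builds a small constructed site, measures the free volume of the standard
inclusion box (12 x 12 x 15 A at (0, 0, 8)) at 1.0 and 0.5 A grid spacing,
and demonstrates that a rigidly displaced copy gives the same volume after
C-alpha alignment onto the reference.
"""

import numpy as np

from fenmor.core import Atom, Structure
from fenmor.pocket import InclusionBox, align_to_reference, pocket_volume

rng = np.random.default_rng(4)
pts = rng.uniform(-4.5, 4.5, (14, 3)) + np.array([0.0, 0.0, 8.0])
atoms = [Atom("CA", "C", 100 + i, "ALA", "A", p) for i, p in enumerate(pts)]
site = Structure(atoms, id="toy-site")
box = InclusionBox((0.0, 0.0, 8.0), (12.0, 12.0, 15.0))

for spacing in (1.0, 0.5):
    res = pocket_volume(site, box, spacing=spacing)
    print(f"spacing {spacing:.1f} A: volume {res.volume:7.1f} A^3 "
          f"({res.n_points_free}/{res.n_points_total} grid points free)")

# rigid motion + alignment leaves the volume unchanged
th = np.radians(35.0)
rot = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
moved = site.with_coords(site.coords @ rot.T + np.array([11.0, -4.0, 2.0]))
aligned = align_to_reference(moved, site, site_residues=[a.residue_seq for a in atoms])
print("volume after rigid motion + alignment:",
      round(pocket_volume(aligned, box).volume, 1), "A^3")
# the two spacings agree within a few percent (grid-convergence) and the
# aligned copy reproduces the reference volume exactly.
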