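"""Two-mode binding trajectory: geometry metrics and mode classification.

Generates a synthetic receptor-ligand trajectory that switches between the
salt-bridge (D147) and hydrogen-bond (H297) anchoring modes, computes the
per-frame anchor distances and the ligand's vertical position, and labels
each frame.  The H297 mode should sit about 1 Angstrom deeper in the
receptor and be recovered near-perfectly from the 3.5 A distance rule.
"""

import numpy as np

from fenmor.geometry import delta_z, min_distance, vertical_angle
from fenmor.modes import assign_modes
from fenmor.synthetic import ToyComplexSpec, simulate_mode_trajectory

traj, truth, toy = simulate_mode_trajectory(ToyComplexSpec(n_frames=2000, seed=1))

d_d147 = min_distance(traj, toy.amine_selection(), toy.carboxylate_selection())
d_h297 = min_distance(traj, toy.amine_selection(), toy.ne2_selection())
labels = assign_modes(d_d147, d_h297)
dz = delta_z(traj, toy.ligand_selection(), toy.receptor_selection())
angle = vertical_angle(traj, toy.ligand_selection())

agree = np.mean([l.value == ("NEITHER" if t == "UNBOUND" else t)
                 for l, t in zip(labels, truth)])
print(f"frames: {traj.n_frames}, mode recovery vs ground truth: {100 * agree:.2f}%")
for mode in ("D147", "H297"):
    mask = np.array([l.value == mode for l in labels])
    print(f"{mode}: occupancy {mask.mean():5.1%}  "
          f"dZ {dz[mask].mean():.2f} A  vertical angle {angle[mask].mean():.1f} deg")
# dZ drops by ~1 A and the ligand straightens (30 -> 15 deg) going D147 -> H297,
# i.e. the deeper mode holds the ligand lower and more upright.
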