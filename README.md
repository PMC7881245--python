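# fenmor

Analysis toolkit for ligand binding modes in the μ-opioid receptor (mOR),
built around the case of fentanyl. Fentanyl's protonated piperidine amine can
anchor to the receptor in two distinct ways: the classical salt bridge with
Asp147 (Asp^3.32^), shared with morphinan opiates, and a deeper pose in which
the amine donates a hydrogen bond to the Nε atom of a neutral His297
(His^6.52^) in its HID tautomer. `fenmor` implements the analysis layer used
to characterise such two-mode binding from simulation output: geometric
binding-mode classification, residue contact fingerprinting with Tanimoto
comparison, titration-state analysis with macroscopic pKa estimation,
grid-based pocket volume, and a weighted-ensemble (WE) resampler with a toy
Brownian propagator — plus synthetic-data generators so every stage is
testable against known ground truth without any downloads.

It is a library first: import the modules from Python, or start from the
short narrative scripts in `examples/`. A thin `fenmor` CLI mirrors the
stages for shell use.

## The quantities it computes

- **Binding modes.** A frame is *D147-bound* when the minimum distance from
  the piperidine nitrogen to the Asp147 carboxylate oxygens is ≤ 3.5 Å, and
  *H297-bound* when the amine-N to His297-Nε distance is ≤ 3.5 Å; the
  classifier is total (BOTH / NEITHER cover the rest). Supporting metrics:
  ΔZ, the ligand-receptor center-of-mass separation along the membrane
  normal with the flexible terminal residues (52–65, 336–347) excluded from
  the receptor center; the ligand's vertical (principal-axis) tilt angle;
  sidechain χ₂ dihedrals; receptor-fit/ligand-evaluated RMSD.
- **Contact fingerprints.** Residue *i* is in contact when any sidechain
  heavy atom is within 4.5 Å of any ligand heavy atom; profiles are contact
  fractions over a frame window, binarised at 25%, compared with the
  Tanimoto coefficient
  `S_AB = Σ x_iA x_iB / (Σ x_iA² + Σ x_iB² − Σ x_iA x_iB)`.
- **Titration.** Discrete per-frame His states (HID/HIE/HIP) or acid states
  across a pH ladder; the macroscopic pKa comes from a weighted Hill fit of
  the deprotonated fraction `f(pH) = 1 / (1 + 10^{n (pKa − pH)})`, with
  bootstrap uncertainty and state-distance coupling tables.
- **Pocket volume.** POVME-style: binding-site Cα alignment, a fixed
  inclusion box (default 12 × 12 × 15 Å at (0, 0, 8)), free grid points
  outside the van der Waals radii × spacing³.
- **Weighted ensemble.** Walkers binned on a progress coordinate; each
  resampling splits the highest-weight walker of under-filled bins and
  merges the two lowest-weight walkers of over-filled bins (survivor drawn
  proportionally to weight), conserving total probability exactly.

## Worked example

```python
import numpy as np
from fenmor.synthetic import ToyComplexSpec, simulate_mode_trajectory
from fenmor.geometry import min_distance, delta_z
from fenmor.modes import assign_modes

traj, truth, toy = simulate_mode_trajectory(ToyComplexSpec(n_frames=2000, seed=1))
d1 = min_distance(traj, toy.amine_selection(), toy.carboxylate_selection())
d2 = min_distance(traj, toy.amine_selection(), toy.ne2_selection())
labels = assign_modes(d1, d2)
dz = delta_z(traj, toy.ligand_selection(), toy.receptor_selection())
for mode in ("D147", "H297"):
    m = np.array([l.value == mode for l in labels])
    print(mode, round(m.mean(), 3), round(dz[m].mean(), 2))
```

prints

```
D147 0.678 8.4
H297 0.179 7.58
```

i.e. the trajectory spends ~68% of its frames in the salt-bridge mode at a
ΔZ of 8.4 Å and ~18% in the hydrogen-bond mode, which sits about 1 Å deeper
— the displacement that separates the two poses. `examples/01–05` walk
through each capability the same way (fingerprints and Tanimoto, titration
and pKa, pocket volume, weighted ensemble); `examples/06` shows how to run
the rotamer and pocket-volume analyses on the downloaded mOR crystal
structures (active 5C1M, inactive 4DKL).

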