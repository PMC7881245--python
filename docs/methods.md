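# Methods

This note documents the models, conventions and numerical choices behind
`fenmor`, and what the synthetic generators do and do not emulate.

## Structures, trajectories, selections

Structures are parsed from PDB with gemmi, keeping author residue numbering
(the literature on mOR cites author numbers such as Asp147, His297) and
retaining hydrogens with a heavy-atom flag; wherever a rule says "heavy
atoms", hydrogens are excluded at the point of use. Alternate locations are
resolved to the highest-occupancy conformer, ties toward altloc `A`, giving a
deterministic single-conformer model. Trajectories are a fixed topology plus
coordinate frames, read from multi-model PDB or a plain whitespace table
(`frame atom_index x y z`); no binary formats are involved. The selection
language is a conjunction of simple clauses (`resid 52-65,336-347`,
`name CA`, `resname FEN`, `chain A`, `sidechain`, `heavy`); *sidechain*
means everything except N, CA, C, O, OXT and the hydrogens bonded to them,
so CB is sidechain. Empty selections warn rather than failing silently.

## Geometric observables

* **Minimum distance** between two selections is the exact pairwise minimum
  per frame. The D147 anchor distance defaults to amine-N →
  {OD1, OD2}; a whole-group minimum-heavy-atom variant is available by
  passing broader selections, since the two phrasings of the definition
  differ only in the selections supplied.
* **ΔZ** is the absolute difference of mass-weighted center-of-mass z
  between the ligand and the receptor core, the z axis being the membrane
  normal of the input frames. The flexible N-terminal (52–65) and
  C-terminal (336–347) stretches are excluded from the receptor center by
  default. Mass weighting uses standard atomic masses (gemmi element
  tables); geometric centers are available by flag. ΔZ is reported unsigned
  because the quantity of interest is the ligand's depth.
* **Vertical angle** is the angle between the ligand heavy-atom principal
  axis (largest-eigenvalue eigenvector of the coordinate second-moment
  tensor) and z, folded into [0°, 90°]. Near-collinear ligands keep a
  well-defined long axis; a warning marks the degenerate transverse axes.
* **χ₂ dihedrals** use the IUPAC atom quadruples (Trp/Phe/Tyr:
  CA–CB–CG–CD1; His: CA–CB–CG–ND1; Asp: CA–CB–CG–OD1) with the standard
  sign convention, verified against Biopython's dihedral routine. Signed
  range is (−180°, 180°]; a mirrored structure negates the angle.
* **Superposition/RMSD** is a Kabsch least-squares fit (SVD with the
  determinant correction, so no reflections) with independent fit and
  evaluation selections. The WE progress coordinate is receptor-Cα-fit,
  ligand-heavy-evaluated RMSD versus the starting pose; this choice (the
  superposition frame being otherwise under-determined) is configurable.

## Contacts and fingerprints

A residue-ligand contact in a frame means some sidechain heavy atom within
4.5 Å (inclusive boundary) of some ligand heavy atom. Contact profiles are
per-residue fractions over a frame window; glycine (no sidechain heavy
atoms) reports 0. The display/analysis filter keeps residues reaching 25%
in at least one of a set of profiles. Fingerprint matrices apply the same
rule per ligand substituent group. Binary profiles for Tanimoto comparison
binarise at the 25% threshold by default — the same threshold as the
display filter, exposed as a parameter since reasonable alternatives exist
(e.g. any-presence at 0). Profiles are aligned on the union of residues,
absent residues counting 0; the coefficient is undefined (raises) when both
profiles are empty. All chains present in the input are analysed.

## Pose clustering

Hierarchical agglomerative clustering (scipy, average linkage by default)
on the pairwise ligand heavy-atom RMSD matrix, cut at a 3 Å distance
threshold. Frames are pre-aligned to frame 0 on receptor Cα so the matrix
measures pose differences within the receptor frame; disabling alignment
switches to pairwise best-fit RMSD (conformational differences only).
Clusters are renumbered by descending size; the representative is the
member minimising mean RMSD to its cluster, ties toward the lowest frame
index. Average linkage was chosen as the common trajectory-analysis
default; the linkage is a parameter.

## Titration analysis

Input is a discrete per-frame state series per pH (His: HID/HIE/HIP; acids
and amines: PROT/DEPROT) — the discretised output of constant-pH
simulations, not the λ-dynamics itself. An adapter thresholds raw titration
coordinates (λ < 0.2 protonated, λ > 0.8 deprotonated, mixed frames
discarded). The deprotonated fraction (His: HID + HIE, since HIP is the
protonated species) is fitted with a generalised Henderson–Hasselbalch
(Hill) curve by least squares weighted by per-pH frame counts; the fit
refuses to extrapolate when the fraction never leaves 0 or 1 inside the pH
window, and flags a fitted pKa outside the window. Uncertainty comes from a
seeded bootstrap over frames (200 resamples by default). Occupancies at
physiological pH 7.4 are linearly interpolated between the bracketing 7.0
and 7.5 replicas (nearest-replica readout available). The coupling table
reports conditional distance mean/sd and occupancy per (pH, state), leaving
never-sampled cells absent rather than zero.

## Pocket volume

After rigid superposition on the Cα atoms of the 21 orthosteric-site
residues (75, 124, 127, 133, 144, 147, 148, 151, 152, 232, 233, 236, 240,
293, 296, 297, 300, 318, 319, 322, 326), a cell-centered grid tiles the
inclusion box (default 12 × 12 × 15 Å at (0, 0, 8), cells anchored at the
box corner, 1.0 Å spacing). A grid point is occluded when inside the Bondi
van der Waals radius of any remaining heavy atom; volume = free points ×
spacing³. Waters, ions, lipids and ligands are stripped by residue name
before the calculation. No probe inflation and no contiguity filtering are
applied by default; both exist as parameters, and together with the grid
spacing they are the knobs that reconcile small differences against other
grid-volume implementations — grid-settings sensitivity on the fixtures
used here is under 5% on spacing halving.

## Weighted ensemble

Walkers carry a state vector, a probability weight and a lineage id. Bins
are half-open intervals `[b_i, b_{i+1})` over strictly increasing
boundaries, with an overflow bin above the last boundary; the ligand-RMSD
boundary list used for receptor–ligand work (0 to 10 Å in 0.05–0.5 Å
steps, then overflow) ships as a constant. Each iteration propagates every
walker for τ, then resamples each occupied bin to exactly the target count:
under-filled bins repeatedly split their highest-weight walker (ties to the
lowest lineage id) into two half-weight copies; over-filled bins repeatedly
merge their two lowest-weight walkers, the survivor drawn with probability
proportional to weight and inheriting the pair's combined weight. This
keeps total weight exactly conserved (machine precision) and the weighted
mean of any observable unbiased in expectation. There is no recycling/sink:
the sampler is exploratory, and manual rebinning is done by restarting with
a new scheme. The per-bin target is a required parameter (practice varies
between four and five for this system). MD propagation is out of scope; the
`Propagator` interface takes any stochastic dynamics, and the shipped
overdamped Brownian (Euler–Maruyama) propagator on 1-D model potentials
exercises the protocol end to end. A single seeded generator drives
propagation and merge decisions, making runs bit-reproducible.

## Synthetic generators

`make_toy_complex` builds a ~60-residue pseudo-receptor around a stylised
24-heavy-atom 4-anilidopiperidine ligand: an Asp-like carboxylate site and
a His-like Nε site placed 120° apart around the pocket axis, 2 Å apart
laterally, with the His site ~1 Å deeper — the displacement separating the
two binding modes. Satellite sidechain pseudo-atoms around the pocket give
the two modes overlapping but distinct contact sets; terminal tails at
extreme z exercise the ΔZ exclusion rule; a bulk ring is shifted so the
D147-mode ligand sits 8.4 Å above the receptor-core center (the H297 mode
then lands near 7.4 Å). Mode templates carry a vertical tilt (30° for the
salt-bridge pose, 15° for the more upright deep pose, encoding the
qualitative reorientation between modes) in addition to the z-rotation /
translation / z-offset that define the displacement. Templates are
validated against their defining distances at build time.

`simulate_mode_trajectory` draws a Markov mode sequence whose stationary
distribution equals the requested occupancies (default 0.7/0.2/0.1 for
D147/H297/unbound, stay-probability 0.9) and adds isotropic Gaussian noise
(default sd 0.2 Å) to the ligand template; the receptor is rigid. Ground
truth labels are returned, and the generator warns if noise violates the
defining distances in more than 1% of frames.

`simulate_titration` draws per-frame protonation Bernoulli variables from
the Hill form at each pH (16 replicas, 2.5–9.5 in 0.5 steps by default),
then assigns neutral frames to HID with a tautomer-bias probability,
overridden to certainty when a paired distance is below 4 Å (the
state-distance coupling rule). Preset conditions reproduce the reported
state populations of His297 in the apo receptor (pKa 6.8; 64/12/24%
HIE/HID/HIP at pH 7.4), the salt-bridge complex (pKa 7.3) and the
hydrogen-bonded complex (pKa 6.7, HID-dominant), and of Asp114 (pKa 4.8);
the Hill slopes and biases are back-computed from those populations. A
companion generator draws state-conditional distances (3.0 ± 0.22 Å for
HID, 7.4 ± 0.72 Å for HIE, 8.0 ± 0.5 Å for HIP) for coupling-table
analyses.

What the generators do **not** emulate: excluded volume, receptor
flexibility, realistic membrane/helix geometry, ligand conformational
sampling, autocorrelated titration dynamics or replica exchange. Passing
tests therefore demonstrate correctness of the analysis layer on data with
the stated statistical structure, not fidelity of any physical simulation.

## Problem sizes and determinism

Default analysis sizes were chosen so the full test suite runs in well
under a minute of CPU: trajectories of 500–10,000 frames, 5,000 frames per
pH for parameter-recovery checks, 1,500 WE iterations (histogram averaged
over the last 1,000) against a 512-chain unbiased Brownian oracle, pose
clustering on strided subsets of ≤ 300 frames. Every stochastic component
takes an explicit seed; the pipeline writes a manifest (config hash, seed,
package version) sufficient to reproduce all outputs bit-exact.

## Known limitations

Chain identifiers are single characters on PDB output; insertion codes are
not modelled. The contact machinery is O(frames × pocket atoms) and meant
for analysis-scale inputs, not million-frame production data. The pocket
volume carries no contiguity segmentation, so disconnected free pockets
inside the box are counted together. Rate estimation between binding modes
is deliberately out of scope.
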