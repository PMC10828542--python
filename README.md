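# splitperox

Comparative structural and dynamical analysis of two biotechnologically
important heme peroxidases — horseradish peroxidase (HRP, 308 residues,
PDB 1H5A) and soybean cytosolic ascorbate peroxidase (APX, 250 residues,
PDB 1OAG) — and of their engineered split variants, sHRP (6 stabilising
mutations, split between residues 213–214) and sAPEX2 (9 mutations,
split between residues 200–201). Split peroxidases are cut into two
inactive fragments that regain activity on reconstitution, which makes
them attractive reporters for protein–protein interaction assays; the
question the analyses address is which system is structurally better
suited to that use.

The package is aimed at structural bioinformaticians who want each
analysis step as a tested, composable function rather than a one-off
script: sequence-level variant construction and N-glycosylation sequon
scanning, rigid-body superposition, MD-style trajectory statistics,
solvation-shell counting, essential dynamics and conformational
clustering. A synthetic-trajectory generator with known ground truth
stands in for long MD runs so that every statistic can be validated
against closed forms at desk scale.

## Methods at a glance

- **Sequon scan** — potential N-glycosylation sites follow
  Asn–X–Ser/Thr with X ∉ {Pro, Asp}; positions are reported in crystal
  numbering. HRP carries 9 sites, APX none; the N255D mutation leaves
  sHRP with 8.
- **Kabsch superposition** — the proper rotation R (det R = +1, smallest
  singular value sign-corrected) and translation minimising
  √(Σᵢ wᵢ‖R xᵢ + t − yᵢ‖² / Σᵢ wᵢ) over paired Cα atoms, paired either by
  residue number or through a global sequence alignment (BLOSUM62, gap
  open 10 / extend 0.5).
- **RMSF** — per residue, √⟨‖x_i(t) − ⟨x_i⟩‖²⟩ of the Cα about the
  time-mean structure of the aligned trajectory. For isotropic Gaussian
  fluctuations of amplitude σ per coordinate this converges to σ√3.
- **Trajectory map** — a frames × residues matrix whose entry (t, i) is
  the Euclidean distance between residue i's mass-weighted backbone
  (N, CA, C, O) centre of mass in frame t and in the starting frame of
  the aligned trajectory; its windowed mean ± SD over the trailing
  frames summarises late-trajectory drift.
- **Solvation shells** — waters counted by minimum distance of the
  water oxygen to any atom of the target (heme group, distal His side
  chain, Fe), 5 Å counting shell, 3 Å occupancy grid, minimum-image
  convention under an orthorhombic box.
- **Essential dynamics** — eigendecomposition of the covariance of
  aligned Cα coordinates; explained fraction λᵢ/Σλ; a second system is
  projected onto the reference's components over shared residues so
  both occupy one PC1–PC2 plane.
- **Gromos clustering** — iterative neighbour counting under a pairwise
  fitted-RMSD cutoff (default 1.0 Å); each cluster's representative is
  its medoid.

## Worked example

```python
import splitperox as sp

_, hrp = sp.load_reference_sequence("HRP")
print([h.asn_pos for h in sp.scan_sequons(hrp)])
# [13, 57, 158, 186, 198, 214, 255, 268, 286]

shrp, fragments = sp.apply_variant(hrp, sp.load_variant_spec("sHRP"))
print(sp.hamming(hrp, shrp), len(fragments[0]), len(fragments[1]))
# 6 213 95

helix = sp.make_helix(20)
traj, truth = sp.make_trajectory(helix, sp.SyntheticSpec(n_frames=5000, sigma=0.5, seed=1))
print(round(sp.rmsf(traj).rmsf.mean(), 3))   # ~0.866 = 0.5 * sqrt(3)
```

The numbered drivers under `analysis/` run the full comparative story
and print what they find; e.g. `python analysis/01_sequence_comparison.py`
reports the sequon table above, the 6/9 mutation counts, the split
fragment sizes (213+95 and 200+50 residues) and a 25.0% global sequence
identity between HRP and APX, and `python analysis/04_stability_analysis.py`
shows the split system's windowed backbone displacement
(0.242 ± 0.020 Å) sitting well below its wild type's (0.765 ± 0.063 Å)
under the generated conditions. Tables land in `results/`, bulky
trajectory files in `scratch/`.

A `splitperox` CLI exposes each stage (`seqscan`, `variant`, `features`,
`superpose`, `align`, `rmsf`, `trajmap`, `contacts`, `solvation`,
`occupancy`, `pca`, `cluster`, `simulate`, `compare`); `compare` runs
the whole workflow over a JSON config and writes a side-by-side report.

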