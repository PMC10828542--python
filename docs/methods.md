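# Methods

This note records the models and conventions behind each analysis, the
parameters that matter, what the synthetic data does and does not
emulate, and the design choices made where more than one reasonable
convention exists.

## Sequence layer

Reference sequences for HRP C1A (308 aa, numbered 1–308 as in the 1H5A
crystal structure) and soybean cytosolic APX (250 aa, numbered 1–250
with the initiator methionine as residue 1, matching 1OAG-based site
numbering) are bundled as FASTA. All site reports use these numberings,
which is why residue numbers are always taken verbatim from input files
and never renumbered: the catalytic residues (Arg38/His42 in both
numberings), the proximal histidines (His170 in HRP, His163 in APX) and
every mutation list are defined in them.

**Sequon rule.** A potential N-glycosylation site is Asn–X–Ser/Thr with
X any residue except proline *or aspartate*. The Asp exclusion is
deliberately stricter than the textbook Pro-only rule; it is the rule
under which HRP has exactly the nine sites 13, 57, 158, 186, 198, 214,
255, 268, 286 and sHRP the eight that survive N255D. Windows truncated
at the C-terminus never match; overlapping sites are all reported.

**Variants.** A variant spec is a list of point substitutions plus an
optional split position (`split_after=k` cuts between residues k and
k+1). Each substitution is validated against the wild-type residue it
claims to replace, so a numbering offset fails loudly instead of
silently mutating the wrong site. Sequence analyses of a split enzyme
use the full-length mutated sequence — the analyses model the
*reconstituted* enzyme — and the two fragments are emitted for
completeness.

**Identity.** Global alignment (Needleman–Wunsch with affine gaps) with
BLOSUM62, gap open 10, gap extend 0.5, the gap convention in which a
gap of length L costs open + (L−1)·extend. Percent identity is
identities over aligned columns excluding terminal overhangs; internal
gap columns stay in the denominator, and the gap-column count is
reported so other denominators can be formed. Under these defaults HRP
vs APX gives 25.0% (83 identities / 332 columns); identity conventions
that drop gap columns or normalise by sequence length spread roughly
25–37% on this pair, which is why downstream comparisons treat the
value as convention-dependent with a tolerance of a few points.

## Superposition

Kabsch's SVD solution with the determinant sign correction, so the
rotation is always proper (no reflections); weights optional and
normalised. Structure-vs-structure superposition pairs Cα atoms only —
across two proteins at ~25–28% identity, Cα pairing via a global
sequence alignment (aligned non-gap columns) is the only well-defined
atom correspondence; identical-residue-number pairing is available for
same-protein comparisons. Trajectory alignment fits every frame's
selection (default Cα) to frame 0 and applies the fitted transform to
all atoms. Degenerate point sets (n < 3 or collinear) are rejected.

## Stability statistics

Two reference conventions coexist deliberately:

- **RMSF** is measured about the *time-mean* structure (standard MD
  practice), on the Cα of each residue.
- The **trajectory map** measures displacement from the *starting*
  frame: entry (t, i) = |COM_bb(i, t) − COM_bb(i, 0)| with the backbone
  COM mass-weighted over N, CA, C, O. Residues missing backbone atoms
  use the available subset (with a warning); residues with none yield a
  NaN column that is excluded, with a count, from window statistics.

The **windowed mean displacement** takes, for each frame in the window,
the mean displacement over residues, then reports the mean and the
*sample* SD (ddof = 1) of that per-frame series. The SD could equally be
taken over all residue-frame entries; that pooled variant is exposed
behind a flag (`pooled_sd=True`) but the per-frame-mean convention is
the default because the quantity of interest is the drift of the
chain-average displacement, not the spread across residues. The default
window is the trailing 40% of frames.

Under the generator's isotropic Gaussian model (σ per coordinate), RMSF
converges to σ√3; fitting a trajectory on its own noisy selection
absorbs part of the fluctuation (≈ a factor √(1 − 6/(3N)) for N fitted
atoms), so closed-form recovery tests use trajectories without rigid
motion, where no alignment is needed.

## Structural features

- Contact maps: all-pairs Cα distances on a single (equilibrated)
  structure, contact iff distance strictly below the cutoff
  (default 12 Å). A trajectory-averaged variant can be formed by the
  caller; the single-structure form is the default comparison object.
- Disulfides: CYS SG pairs within 2.5 Å (canonical S–S bond ≈ 2.05 Å,
  margin for coordinate error), greedy nearest-first pairing so each SG
  joins at most one bridge.
- Ions: single-atom hetero residues of the element (default Ca).
- Proximal histidine: the His whose NE2/ND1 lies nearest the single
  heme Fe and within 3.0 Å (a Fe–N coordinate bond is ≈ 2.1 Å). One
  published feature table lists the APX proximal histidine as His174
  while the methods of the same source say His163; the detector reports
  whatever the geometry gives and does not resolve that inconsistency
  by fiat.
- The feature report composes these with the sequon scan and an
  optional Hamming distance to a reference sequence; it has no state of
  its own, a property the tests assert.

## Solvation

"Within r of the heme" means the minimum distance from the water
*oxygen* to *any* atom of the target — the semantics of VMD-style
`within` selections — not distance to a centre of mass. Waters are
residues HOH/SOL/TIP3/WAT with oxygen atoms OH2/OW/O. The distal
histidine target is the side chain only (backbone excluded). Two radii
serve two analyses: 5 Å for counting series, 3 Å for the occupancy
grid (fraction of frames a voxel holds ≥ 1 water oxygen, restricted to
voxels within the shell of the region, 0.5 Å voxels). Counting applies
the minimum-image convention when an orthorhombic box is present. The
series SD is over frames; aggregation over replicas is left to the
caller.

## Essential dynamics and clustering

PCA diagonalises the (non-mass-weighted, ddof = 1) covariance of the
flattened, aligned Cα coordinates about their time mean. To compare two
systems in one plane, the second system is projected onto the *first*
system's components over the residues common to both (centring with the
reference mean so the origins coincide); the alternative — a joint PCA
of the concatenated trajectories — is provided as a separate function.
Projection onto a reference subspace was chosen as the default because
it asks a sharper question (how much of the reference's essential
motion does the variant explore?) and keeps the reference's axes
interpretable.

Clustering is the neighbour-counting scheme standard in MD practice:
pairwise fitted RMSD, the frame with most neighbours within the cutoff
(ties → lowest frame index) seeds a cluster of itself plus its
neighbours, members are removed, repeat. Default cutoff 1.0 Å. The
"middle structure" of a cluster is interpreted as its medoid (minimum
mean RMSD to the other members) — an interpretation, made explicit
here. The pairwise matrix is O(T²) fits, which bounds practical use to
a few hundred frames; the analyses cluster only the trailing window.

## Synthetic data

The generator emulates an *aligned protein trajectory* as per-atom
isotropic Gaussian noise with a per-residue amplitude σ (Å per
coordinate), optionally wrapped in per-frame global rigid motion
(rotation about the centroid with a given angular SD; translation with
a given per-component SD). Waters are single-oxygen OH2/HOH particles
rejection-sampled so that their minimum distance to a chosen target
lies in a controlled band inside or outside a shell, with per-frame
inside counts recorded in a manifest. A Gaussian fluctuation model (not
an elastic network) was chosen because every statistic the package
computes has a closed form or exact oracle under it — RMSF = σ√3, flat
PCA spectra for uniform σ, planted shell counts — which turns the test
suite into parameter-recovery checks. Fixed seed ⇒ bitwise-identical
output.

What it does *not* emulate: correlated collective motions, anisotropy,
solvent dynamics, force-field physics, glycans. Passing tests therefore
demonstrate the correctness of the statistics, not the realism of any
simulated ensemble; conclusions about the real enzymes require real
trajectories.

`make_peroxidase_model` additionally builds a *schematic synthetic
stand-in* for a peroxidase crystal: the real sequence threaded onto an
ideal helix (rise 1.5 Å, twist 100°, radius 2.3 Å — reproducing the
3.8 Å consecutive-Cα spacing), SG atoms planted at 2.03 Å for chosen
disulfide pairs, an NE2 on every histidine, a minimal heme with its Fe
2.1 Å from the chosen proximal His, and monoatomic calcium ions. Its
geometry is deliberately unphysical; it exists so the feature detectors
can be exercised against planted ground truth without distributing
crystal-structure coordinates. Analyses of the real 1H5A/1OAG
structures fetch them from the RCSB PDB at run time.

## Analysis conditions

The comparative drivers (analysis/03–06) use two systems on a
25-residue fold over 400 frames: "wild type" σ = 0.6 Å and "split"
σ = 0.2 Å per coordinate, both with 5° / 1 Å rigid-body jitter and 24
planted shell waters alternating 16/18 inside a 5 Å shell. These sizes
keep each statistic's sampling error well below the planted effect
(a 3× amplitude ratio) while every script completes in seconds; the
closed-form RMSF recovery checks use 5000 frames on a 20-residue fold,
where the σ√3 estimate is within a few tenths of a percent.

## Known limitations

- PDB parsing keeps only blank/'A' altlocs and infers missing element
  columns from atom names; mmCIF and binary trajectory formats (XTC,
  DCD) are out of scope — multi-model PDB and a plain per-frame XYZ
  text format are the interchange formats.
- Residue counts from SEQRES and from resolved ATOM records can differ
  in real crystal structures; both are exposed and SEQRES is preferred
  for sequence extraction.
- The O(T²) clustering and the per-frame Python loops in alignment are
  sized for hundreds-of-frames analyses, not for full production MD.
- Cavity/tunnel volumes, secondary-structure assignment, glycan
  geometry and docking are out of scope.
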