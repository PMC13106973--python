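# Methods

`pmhcnet` predicts, for a peptide presented by a class I MHC molecule, both
a binding-affinity score and an all-atom 3D model of the bound peptide, in
one forward pass of a rigid-frame attention network.  This note records the
model, its assumptions, the numerical choices, and what the synthetic test
system does and does not demonstrate.

## Representation

**Frames.** Each residue backbone is treated as a rigid triangle
(N–Cα–C, bond angle ≈ 109°) carried by a *local frame*: a unit quaternion
plus a translation in Å, mapping the canonical triangle (Cα at the origin,
C on +x, N in the xy-plane) into the global coordinate system.  Quaternions
are renormalized after every composition and stored with w ≥ 0 (q and −q
are the same rotation).  Frame algebra is equivalent to 4×4 homogeneous
matrix algebra; the test suite checks this to 1e-9 on random pairs.

**Torsion parameterization.** Side chains are generated from the frame via
rigid groups: each torsion (φ, ψ, ω, χ1–χ4) owns the set of atoms it
rotates.  The ω group is empty; the φ group holds only the amide hydrogen,
which is placed on demand (never part of the heavy-atom arrays, and absent
for proline); the ψ group holds the carbonyl O; the χ groups hold the
side-chain atoms distal to each rotatable bond.  Heavy atoms live in a
fixed ≤14-slot layout per residue type: slots 0–4 are always
N, CA, C, O, CB, the remainder follow chemical-component-dictionary order
(tryptophan fills all 14).  Ideal internal coordinates — group-local atom
positions and inter-group transforms — are derived at first use from the
ideal residue geometries bundled with biotite (the PDB chemical component
dictionary); the derivation code in `pmhcnet.residues` is the single source
of truth, and reconstruction of the ideal residues from the derived tables
is exact to ~1e-15 Å.

**Torsion conventions.** Public angles are degrees in (−180, 180];
internally the network carries (sin, cos) pairs.  φ/ψ/ω follow the
standard inter-residue definitions.  The ψ of a chain's last residue (no
following N) is inferred from the carbonyl O through the sp2-planarity
relation ψ = dihedral(N, CA, C, O) + 180°; this closes the
extract → place → extract round trip, which reproduces heavy atoms to
≤1e-3 Å and angles to ≤1e-4° on random peptides.  ω defaults to trans
(180°) when no prediction is available.

## Features

Every record carries: one-hot peptide and MHC sequences at width c_s = 32
(20 channels used, 21–32 reserved zeros); the MHC proximity matrix
1/(1 + d_ij) with d_ij the shortest heavy-atom distance between residues i
and j; precomputed MHC backbone frames; a cross-attention mask selecting
MHC residues whose nearest heavy atom lies within 15 Å (configurable) of
the groove center; optional ground-truth peptide frames, torsions and
atoms; and the affinity target.  Affinities (Kd or IC50 in nM, treated
identically) are rescaled to 1 − log50000(value), so 1 nM ↦ 1, 50 µM ↦ 0;
a binder is a measurement strictly below 500 nM, which on the transformed
scale sits at ≈ 0.426.

All structures are superposed onto a single reference orientation with the
groove center at the origin before featurization (least-squares fit on
sequence-aligned G-domain Cα pairs, BLOSUM62 global alignment, iterative
outlier rejection at 2.0 Å for 5 cycles, ≥50 % sequence identity required).
The shared orientation is part of the data contract: the network starts
every peptide residue as an identity frame at the origin, so inputs must
agree on where the groove is.

## Network

Four modules, all built on one flat parameter dict over a small in-repo
reverse-mode autodiff engine (`pmhcnet.autograd`):

1. **MHC self IPA** — invariant point attention over the MHC: logits are
   feature dot-products plus a learned per-head scalar times the proximity
   matrix minus a softplus-weighted sum of squared distances between query
   and key points expressed in the fixed MHC frames.  Because point terms
   depend only on inter-point distances and attended points are mapped back
   into each residue's local frame, the module is invariant to any global
   rigid motion applied consistently to the MHC (checked to 1e-5).
2. **Peptide self attention** — standard multi-head attention where
   position enters only through learned relative-offset embeddings.
3. **Cross-attention structure** — peptide queries against the (fixed) MHC
   features and frames; each block updates peptide features and emits a
   frame update (an unnormalized quaternion around w = 1, normalized, and a
   translation scaled by 10 Å per unit) composed onto the current frames;
   after the last block a torsion head predicts (sin, cos) for all seven
   angles and atoms are placed by the rigid-group machinery.  Masked MHC
   residues receive −1e9 logits, which underflow to exactly zero attention:
   perturbing a masked residue's features changes no output bit.
4. **Affinity head** — a shared two-layer perceptron applied per residue;
   the score is the sum over peptide positions, so the head is
   length-agnostic by construction.

Defaults: width 32, 8 heads of dim 8, 4 points per head, 2 MHC blocks,
2 peptide blocks, 4 cross blocks, affinity hidden width 32.  These widths
are this package's choices (the architecture family fixes only the module
structure, c_s = 32, n = 14, and the two-iteration default of the peptide
module).  Residual branches end in 0.1-scaled projections so the stack
starts near-identity but symmetry-broken; the frame-update heads start at
exactly zero so the initial peptide sits at the groove center; each output
head (frame update, torsion, affinity) reads a layer-normalized copy of the
trunk, which decouples head scale from trunk drift and was necessary to
keep full-batch training loss curves smooth enough for the slope-based
early stopper to be meaningful.

## Losses

* **Affinity**: mean squared error on the transformed scale.
* **FAPE** (frame-aligned point error): every predicted peptide atom is
  expressed in every frame's local coordinates on both the predicted and
  true side; the mean clamped distance (clamp 10 Å), divided by a 10 Å
  scale, is invariant to global rigid motions of either structure.  The
  distance uses sqrt(|x|² + ε) − sqrt(ε), which is exactly zero for
  identical structures and smooth at zero.  *Frame set*: the groove-
  proximal MHC frames are appended (identical constants on both sides) in
  addition to the peptide frames.  With peptide frames alone FAPE cannot
  see a rigid displacement of the whole predicted peptide, and training
  verifiably drifts out of the groove while the loss falls; the fixed MHC
  frames anchor the pose.
* **Torsion**: mean squared distance between predicted and true (sin, cos)
  pairs over defined angles — periodic by construction, 4.0 for a 180°
  error.  The ω component doubles as the trans-bias auxiliary signal.
* **Violations** (fine-tuning only): flat-bottom penalties that vanish
  within 12 σ of the literature peptide-bond length (1.329 ± 0.014 Å) and
  the flanking backbone angles (cosine space, σ = 2°), plus a clash term
  penalizing non-bonded inter-residue pairs closer than the Bondi vdW sum
  minus 1.5 Å.  All constants live in `LossConfig`; weights default to 1.

## Training

Adam, lr 1e-3, batch size 16, float32, gradient norms clipped to 0.5 at
every step.  Two phases: phase 1 enables affinity + FAPE + torsion; phase 2
adds the violation terms; the lowest-validation-loss checkpoint of phase 1
initializes phase 2 and the early-stopping state resets between phases.
Early stopping evaluates, after each epoch beyond the 50-epoch patience,
the trailing 50 validation losses: values outside 1.5 IQR of the quartiles
are replaced by the window median, a least-squares line is fitted, and the
phase ends when the slope lies strictly inside (−1e-4, 1e-4).  "Validation
loss" is the total of the currently enabled terms.

One deliberate deviation from the clamp convention: phase 1 trains with
*unclamped* FAPE.  The peptide initializes at the groove center, 8–13 Å
from its target — entirely inside the 10 Å clamp's zero-gradient region —
and with the clamp active the structure provably receives no restoring
gradient once it strays.  The clamp applies from phase 2 on, when
distances are small.

## Synthetic test system

The fixture generator builds a reduced groove — two 14-residue helices over
a 4-strand sheet floor, ~48 residues, ideal geometry, groove center at the
origin — and threads random 9-mers through it from jittered polyproline-
like backbone torsions, with side-chain rotamers chosen greedily
(deterministic order, exact vdW criterion) so every fixture is clash-free,
all-L, and all-trans by construction.  Labels follow a stated rule: the
affinity target is affine in the mean rescaled Kyte–Doolittle hydropathy of
the residues at anchor positions 2 and 9 (mirroring the P2/P9 anchor
biology of real grooves), mapped to Kd through the inverse transform.  The
rule is linear in the anchor one-hots, hence learnable by a closed-form
probe, and the binder/non-binder mix is roughly balanced.

What the fixtures do *not* emulate: real MHC fold geometry and sequence
diversity, peptide conformational strain, experimental noise in affinity
measurements, missing atoms/alternate conformations beyond synthetic test
cases, and any allele generalization.  Passing the suite therefore
demonstrates the correctness of the machinery (geometry, losses, training
schedule, QC) and the trainability of the network, not predictive accuracy
on real pMHC data — which would require the full training corpus and is
out of scope for a desk-scale build.

The training demonstration deliberately overfits 8 fixture complexes
(validation stream = training records, an explicit opt-in in `fit`),
echoing at reduced scale the first-phase goal of driving peptide Cα-RMSD
from ~8–9 Å (the groove-center start) to ~1 Å.  On the documented protocol
(fixture seed 11, model/training seed 0, 1 MHC block, 2 cross blocks,
≤500 epochs per phase) the final model reaches mean training Cα-RMSD
≈ 0.8 Å and affinity MSE ≈ 6e-4 in a few minutes on one CPU.  Convergence
speed varies with the random draw of peptides and weights; the protocol
constants are part of the documented study conditions.

## Structure QC

Clash detection lists every heavy-atom pair closer than the sum of Bondi
vdW radii (C 1.70, N 1.55, O 1.52, S 1.80 Å), with the stated exceptions:
hydrogens; same-residue pairs; backbone–backbone pairs of peptide-bonded
residues; proline side chains against a bonded neighbor's backbone; and
cysteine SG–SG pairs that could be disulfide bonded.  Following the
evaluation protocol, per-model QC runs on the modeled peptide chain.
Chirality is the sign of det(N−Cα, C−Cα, Cβ−Cα) — Cβ serves as the fourth
reference point, an interpretation the three backbone atoms alone would
under-determine — with glycine achiral.  ω windows are closed: trans for
|ω| ≥ 160°, cis for |ω| ≤ 20°, otherwise "other".  Anchored Cα-RMSD fits
the model's G-domain Cα atoms onto the reference's (sequence-aligned,
first two and last reference positions excluded, as their conformation
varies between structures), applies the transform to the whole model and
reports RMSD over peptide Cα atoms only.

## Degenerate inputs and tie-breaks

Collinear backbone atoms raise; non-unit quaternions beyond 1e-6 raise;
undefined-but-required torsions raise naming residue and angle; missing
dihedral atoms flag angles undefined instead of raising; chain breaks
(C–N > 2 Å) make spanning torsions undefined; alternate locations keep the
highest-occupancy conformer; duplicate dataset ids raise.  The greedy
rotamer search breaks ties by grid order, making fixtures bit-reproducible.

## Known limitations

* The numpy autodiff engine is single-threaded and desk-scale; the package
  trains toy systems in minutes but is not meant for the full corpus.
* Affinity generalization from 8 structural records is not expected and not
  claimed; the overfit demonstrates trainability of the joint objective.
* The cross-mask rule (distance to the groove center) is a geometric
  stand-in; masks may also be supplied precomputed.
* mmCIF input and automatic G-domain trimming are out of scope; inputs are
  expected pre-trimmed with configured chain ids.
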