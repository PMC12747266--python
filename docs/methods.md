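# Methods

## Problem and model

`hybridqsar` predicts the potency of small molecules against protein
targets, expressed as log10 of the half-maximal inhibitory concentration
(IC50) in nanomolar. Note the target is log(IC50), not pIC50 — lower values
mean higher potency and no sign flip is applied. The regressor combines two
complementary molecular views:

1. **Graph branch.** Each molecule is a graph of heavy atoms. Node identity
   is a joint (element, hybridization) class — sp3 and sp2 carbon are
   distinct vocabulary entries — drawn from the Cartesian product of 12
   common drug-like elements (C, N, O, S, P, F, Cl, Br, I, B, Si, Se) and 7
   hybridization states, plus one out-of-vocabulary bucket (85 classes).
   The vocabulary id is mapped through a learned 32-dimensional embedding
   and concatenated with 10 numeric atom features (atomic number, degree,
   formal charge, total hydrogen count, aromaticity flag, ring flag, R and
   S chirality flags, smallest-ring size, total valence), linearly
   projected to 128 dimensions and batch-normalized. Two multi-head graph
   attention layers follow (2 heads x 64 dimensions each, concatenated to
   128; LeakyReLU slope 0.2 on the logits). Attention logits are
   conditioned on the 5 bond features (bond-type code, conjugation, ring,
   aromaticity, stereo code) through a learned edge projection, so bond
   chemistry modulates message weights; self-loops with zero bond features
   let every atom attend to itself and keep single-atom molecules
   well-defined. After each attention layer: ReLU, batch normalization over
   nodes, dropout 0.2. Concatenated global mean and max pooling give a
   256-dimensional graph embedding.
2. **Descriptor branch.** A 544-vector per molecule: 512-bit Morgan
   (circular) fingerprint with radius 2 followed by 32 physicochemical
   descriptors, z-score normalized with statistics fitted on the training
   set only. The stack 544 -> 256 -> 128 applies ReLU, batch normalization
   and dropout 0.3 after each linear layer.

The 256-d graph embedding, 128-d descriptor embedding and a raw molecular
size scalar (sum of heavy-atom atomic numbers) are concatenated into a
385-vector and passed through a 64-unit head (ReLU, batch norm,
dropout 0.2) and a final linear layer to the scalar prediction.

## Descriptor registry

The 32 physicochemical descriptors (computed with RDKit, in fixed order):
MolWt, LogP, TPSA, NumHDonors, NumHAcceptors, NumRotatableBonds,
NumAromaticRings, NumAliphaticRings, NumSaturatedRings, RingCount,
FractionCSP3, HeavyAtomCount, NumStereocenters, FormalCharge,
NumHeteroatoms, NumValenceElectrons, MolMR, Kappa1, Kappa2, Kappa3,
BertzCT, NumBridgeheadAtoms, NumSpiroAtoms, HallKierAlpha, Chi0v, Chi1v,
Chi2v, LabuteASA, NHOHCount, NOCount, NumAromaticHeterocycles,
NumAliphaticHeterocycles. The final nine (HallKierAlpha onward) are
standard topological/surface/count descriptors chosen by this package to
fill the registry to exactly 32 slots so the 544-length contract holds;
they are ordinary RDKit descriptors documented here and in
`featurize.PHYSCHEM_NAMES`.

Everything is strictly 2D topology: no conformers, no 3D descriptors, no
partial-charge calculations.

## Data curation

Raw activity tables (CSV in the shape of ChEMBL web-service exports, with
`smiles`, `target_chembl_id`, `standard_value`, `standard_units`,
`standard_type`) pass through, in order:

1. SMILES validation and RDKit canonicalization; multi-fragment inputs
   (salts) are reduced to the largest fragment by heavy-atom count before
   canonicalization (counted but not dropped).
2. Removal of rows whose standard type is not IC50 or whose value is
   missing/non-numeric.
3. Unit harmonization: `nM` kept, `uM`/`µM` converted (x1000),
   case-insensitive; any other unit is dropped and counted. Conversion
   happens before grouping so mixed-unit duplicates take a consistent
   median.
4. Removal of non-positive concentrations (cannot be log-transformed).
5. Collapse of duplicate (canonical SMILES, target) groups to their median
   IC50 (arithmetic mean of the two central values on even counts), then
   log10 of the value in nM.

Every dropping stage increments a provenance counter and the identity
`raw rows = clean samples + total drops` holds on every input; cleaning is
idempotent on its own output.

The train/test split is a seeded uniform permutation at the record level
(compound-target pair), 80/20 by default with `round((1 - f) * n)` training
rows. Record-level splitting means the same compound can be a training
example for one target and a test example for another — faithful to the
curation procedure the pipeline mirrors, but a leakage caveat for chemical
generalization claims; `split(..., by_compound=True)` keeps all records of
a compound on one side instead. The model input carries no target
identity, so identical compounds measured against different targets are
genuinely conflicting labels; this bounds attainable accuracy on pooled
multi-target data and is intentional.

Training-set imbalance across targets is addressed by oversampling: each
target's samples are padded with seeded draws (with replacement) from that
target until all targets match the largest one, once per run before
training, then shuffled.

## Training

Smooth-L1 (Huber) loss with transition beta = 1.0 (the conventional
default; only the loss family is prescribed), Adam with learning rate 1e-3,
L2 weight decay 1e-5 added to gradients, batch size 32, 300 epochs by
default (configurable for desk-scale runs), all seeded: initialization,
dropout masks, batch order and oversampling all derive from explicit seeds,
so identical configurations reproduce identical histories.

Two training refinements are applied by default and can be disabled in
`TrainConfig`:

* **Output-bias initialization** at the training-label mean. Adam's
  per-parameter step is bounded by roughly the learning rate, so at
  lr 1e-3 a zero-initialized output bias cannot traverse the ~3 log-unit
  offset of typical label means within desk-scale epoch budgets; starting
  the bias at the mean removes that artificial transient.
* **Precise batch-norm recalibration**: after each epoch the batch-norm
  running statistics are recomputed in one dropout-free pass over the
  training set. Statistics accumulated during training average activations
  seen under dropout noise and lag the optimized network; recalibration
  makes eval-mode predictions consistent with the network actually being
  optimized. Cost: one extra forward pass per epoch.

No early stopping, no learning-rate schedule, no model selection on the
test curve: per-epoch test metrics are recorded for curve inspection only
and headline metrics are final-epoch. Training runs on CPU.

Evaluation reports R^2, RMSE and MAE on the log scale, overall and per
target with at least two samples; R^2 uses the evaluated group's own truth
mean for the total sum of squares, so per-target values are
self-referential. Zero-variance truth groups yield a flagged record rather
than a number.

## Synthetic data

The fixture generator assembles molecules from a fragment grammar
(substituted benzene, pyridine, pyrimidine, furan, thiophene, naphthalene,
cyclohexane and cyclopentane cores plus short functionalized chains and 22
substituents), which guarantees parseable, reasonably drug-like structures
spanning a spread of ring counts, heteroatom content, flexibility and
lipophilicity without rejection sampling. Generated sets contain exactly
`n_molecules` distinct structures; duplicates and invalid rows are injected
explicitly and deliberately.

Activity tables emulate the statistical shape of curated multi-target IC50
exports: three targets with 4:2:1 size ratios by default (unequal group
sizes at desk scale), activities centered near 1 µM spanning several orders
of magnitude, ~30% of rows emitted in µM units, ~10% of compounds measured
twice with jittered values, and ~5% deliberately invalid rows split across
malformed SMILES, non-positive values, missing units and wrong standard
types. The planted signal is one of:

* `descriptor`: log10 IC50(nM) = 3.0 + 0.6 z(LogP) + 0.5 z(MolWt)
  - 0.4 z(TPSA) + 0.3 z(RotB) + per-target offset (0.5 apart) + N(0, 0.3);
  recoverable by ordinary least squares on the generating descriptors
  (R^2 = 1 at zero noise, checked in tests), and visible to the descriptor
  branch, which receives exactly these quantities among its 544 inputs.
* `substructure`: a +1.5 log-unit shift when the molecule contains an
  aromatic nitrogen (pyridine/pyrimidine-type ring), with positives and
  negatives balanced about 50/50 — a purely topological signal for
  exercising the graph branch with the descriptor branch ablated.

What the generator does **not** emulate: real assay noise structure,
activity cliffs, scaffold clustering, target-specific chemotypes, or the
chemical-space statistics of any real target family. Passing the synthetic
recovery tests demonstrates that the pipeline, featurization and
optimization can extract a planted structure-activity relationship at
realistic noise levels — not that the model attains any particular accuracy
on real bioactivity data, which requires a database export and full-scale
training via the CLI.

## Numerical choices and degenerate inputs

* Autodiff: the neural stack runs on the package's reverse-mode tape over
  NumPy arrays; gradients are validated against central finite differences
  in the test suite (median relative error ~1e-9).
* Zero-variance descriptor dimensions (common for unused fingerprint bits
  on small training sets) z-score to exactly 0 via an epsilon guard
  (1e-8); batch-norm uses eps 1e-5.
* Segment softmax subtracts the per-segment maximum (treated as constant;
  softmax is shift-invariant) for numerical stability; segment max splits
  gradient evenly among ties.
* Single-atom molecules (methane) have no bonds; the self-loop makes
  attention well-defined and mean pooling equals max pooling.
* Atoms without an assigned CIP code carry 0 in both chirality flags;
  smallest-ring size uses the smallest-set-of-smallest-rings convention;
  bond stereo is the toolkit's enumeration code with 0 = none.
* Molecular size excludes implicit hydrogens (heavy atoms only), matching
  the implicit-hydrogen graph convention.
* Mini-batches with fewer than 2 samples are skipped (batch statistics are
  undefined); splits require at least 2 samples; normalizers require at
  least 2 vectors.

## Problem sizes used in the test suite

Structural and oracle checks run on a 25-molecule panel. The capacity
check memorizes a 32-molecule noiseless single-target set for 300 epochs
with regularization (dropout, weight decay) disabled — regularization
exists to prevent memorization, and the check verifies capacity and
gradient flow, not the production configuration. Signal-recovery runs use
1000 molecules (800 train / 200 test) at noise 0.3 log units for up to 100
epochs under the production configuration. These sizes were chosen as the
smallest at which the planted effects are comfortably detectable.

## Known limitations

* No target-identity feature: pooled multi-target training carries
  conflicting labels for compounds measured against several targets.
* 2D topology only; conformation-dependent activity is out of reach.
* The descriptor registry's last nine slots are this package's documented
  choice of standard descriptors, not a canonical set.
* Attention weights are exposed raw (`HybridIC50Model.attention_weights`)
  but no interpretability tooling is built on them.
* The pipeline reads local CSV exports; there is no built-in database
  download — all tests and examples run on local CSVs and synthetic
  fixtures.
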