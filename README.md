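# hybridqsar

Potency prediction for small molecules: a hybrid graph-attention +
descriptor regressor for log10 IC50, with the full bioactivity-curation
pipeline needed to train it from ChEMBL-style activity exports.

## Who this is for

Computational and medicinal chemists doing ligand-based virtual screening:
given measured IC50 values for compounds against one or more protein
targets, train a model that predicts log(IC50) for new structures from
SMILES alone — no cell-line, omics or 3D-structure context required.

## The model

Two parallel branches, fused:

- **Graph branch** — molecules as graphs of heavy atoms whose node classes
  are joint (element, hybridization) tuples: Csp3 and Csp2 are different
  vocabulary entries, so electronic configuration enters the topology
  itself. Eleven atom features and five bond features feed two
  edge-conditioned graph-attention layers (hidden 128, 2 heads); global
  mean + max pooling give a 256-d embedding.
- **Descriptor branch** — a 544-vector (512-bit Morgan fingerprint,
  radius 2, plus 32 physicochemical descriptors: MW, LogP, TPSA, H-bond
  counts, ring counts, kappa shape indices, Bertz complexity, ...),
  z-scored on the training set, through a 544 → 256 → 128 network.

The fusion head concatenates [256 ‖ 128 ‖ molecular size] = 385 → 64 → 1,
predicting log10 IC50 in nM. Training uses smooth-L1 (Huber) loss, Adam
(lr 1e-3, weight decay 1e-5), batch size 32, per-target oversampling, and
dropout 0.2/0.3 with batch normalization throughout. Metrics are R², RMSE
and MAE on the log scale, overall and per target.

The data pipeline applies the standard curation steps: SMILES validation
and canonicalization (largest fragment kept for salts), IC50-only
filtering, nM/µM unit harmonization, removal of non-positive values,
median collapse of duplicate (compound, target) measurements, log10
transform, seeded 80/20 split — with per-stage drop counts recorded so
that raw = clean + dropped always holds.

The neural network runs on a small reverse-mode autodiff core over NumPy
included in the package; chemistry goes through RDKit.

## Worked example

Train on a synthetic activity table with a planted structure–activity
signal (no download needed):

```bash
hybridqsar run-all --out run/ --epochs 30 --seed 7 --n-molecules 300
```

This generates 334 raw rows (including deliberate duplicates and invalid
entries), cleans them to 300 samples across three targets (dropping 4
malformed SMILES, 3 bad values/types, 4 unrecognized units, 4 non-positive
concentrations and collapsing 19 duplicate measurements), trains for 30
epochs and prints the held-out metrics:

```
{"group": "overall", "r2": 0.7885, "rmse": 0.5924, "mae": 0.4873, "n": 60, ...}
```

meaning: on the 60 held-out compound–target pairs the model explains ~79%
of the variance in log IC50, with a typical error of ~0.59 log units
(about 3.9-fold in concentration). `run/` contains the cleaned CSV with a
provenance sidecar, `history.csv` (per-epoch train/test loss, R², RMSE),
`metrics.json` (overall and per-target), a truth-vs-prediction scatter
CSV, and a self-contained checkpoint. Predict for new molecules with:

```bash
hybridqsar predict --model run/checkpoint.npz --smiles-file in.smi --out preds.csv
```

Real data: export activities (standard type IC50) for your targets from
ChEMBL as CSV with columns `smiles`, `target_chembl_id`, `standard_value`,
`standard_units`, `standard_type`, then `hybridqsar prepare`,
`hybridqsar train`, `hybridqsar evaluate` — see `--help` on each
subcommand. Full-scale training (thousands of compounds, 300 epochs) is a
multi-hour CPU job.

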