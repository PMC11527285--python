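# genecaps

Capsule-network + self-attention classification of gene expression,
with single-cell → bulk transfer learning and capsule-level
interpretability.

## The problem

Sepsis diagnosis from blood transcriptomes needs a model that (a)
learns from single-cell RNA-seq of patient PBMCs, (b) transfers to the
bulk platforms (microarray, bulk RNA-seq) actually used in the clinic,
and (c) explains *which gene programs* drive its calls.  `genecaps`
implements such a pipeline end-to-end for computational biologists: a
capsule network groups genes into vector-valued capsules whose norms
act as activities of learned gene programs, a Transformer-style
attention layer reads the capsules out into a probability, and an
occlusion/enrichment suite maps each capsule back to gene sets.

## The model

A log-scale expression vector `x ∈ R^n` passes through:

1. **Primary capsules** — `u_i = W_i x`, `i = 1..8`.
2. **Dynamic routing** (3 iterations) into 20 output capsules of 16
   dims: `c_ij = softmax(b_ij)`, `s_j = Σ_i c_ij w_ij u_i`,
   `v_j = ‖s_j‖²/(1+‖s_j‖²) · s_j/‖s_j‖`, `b_ij += (w_ij u_i)·v_j`.
3. **Multi-head self-attention** — per head `softmax(QKᵀ/√d_k)V` with
   `Q = W_q V′`, `K = W_k V′`, `V = W_v V′`, `d_k = 16`; heads
   concatenated.
4. **Dense head** — 150 sigmoid neurons → logistic output
   `p(sepsis) ∈ (0,1)`.

Training: binary cross-entropy, Adam, batch 32, early stopping on
validation loss.  Transfer: re-initialize the head, train it with the
encoder+attention frozen, then fine-tune everything at a lower rate.
Interpretation: per-gene capsule weights (|w| > 0.06 cut-off),
occlusion-based capsule activation tests, hypergeometric enrichment
(BH-corrected) against any GMT collection, and a capsule–pathway
network.  Details and all defaults: [docs/methods.md](docs/methods.md).

No deep-learning framework is required: the network runs on a compact
reverse-mode autodiff engine over NumPy included in the package.

## Worked example

Everything runs on the built-in synthetic generator, which plants
cell-type marker modules and disease modules into log-scale expression
(single-cell with dropout; bulk cohorts with platform shifts):

```bash
genecaps simulate --cohorts 3 --seed 1 --out sim/
genecaps train --expr sim/expression.tsv --labels sim/labels.tsv \
    --config train.yaml --seed 1 --out ckpt/
```

with `train.yaml` containing `epochs: 15`.  The train command logs one
JSON line per epoch and finishes with held-out test metrics; the run
above printed:

```
{"epoch": 1, "train_loss": 0.3939, "val_loss": 0.12319}
...
{"epoch": 14, "train_loss": 0.01659, "val_loss": 0.08721}
{"test_auroc": 0.9980209925098324, "test_auprc": 0.9982592134130295, "best_epoch": 9}
```

Training early-stopped after epoch 14 and restored the epoch-9 weights:
the capsule network separates held-out case from control cells almost
perfectly when a disease signature is present (test AUROC 0.998).  On a
generator with zero disease effect the same pipeline stays at chance
(held-out AUROC ≈ 0.5).  Transfer and interpretation continue from the
same checkpoint:

```bash
genecaps transfer --pretrained ckpt/ --target sim/bulk_cohort0.tsv \
    --labels sim/bulk_cohort0_labels.tsv --out ckpt_bulk/
genecaps rotate --pretrained ckpt/ --cohorts cohorts.tsv --out rotated/
genecaps interpret --ckpt ckpt/ --expr sim/expression.tsv \
    --gmt sim/modules.gmt --out interp/
```

`interpret` writes the gene-importance table (genes × 8 primary
capsules), per-capsule occlusion attributions, the enrichment table and
the capsule–pathway network; on the example above the planted disease
modules are the top-enriched sets for the most disease-responsive
capsule (BH-adjusted p ≪ 0.05).

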