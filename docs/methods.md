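# Methods

## Model

`genecaps` classifies a sample's gene-expression vector
`x ∈ R^n` (log scale, non-negative) into a sepsis probability through
three blocks.

**Capsule encoder.** A first fully connected layer projects `x` into
`P = 8` primary capsules `u_i = W_i x` (no bias).  Each primary capsule
votes for `J = 20` output capsules through learned transforms
`û_{j|i} = w_ij u_i`, and dynamic routing-by-agreement combines the
votes: starting from logits `b_ij = 0`, each of `T = 3` iterations
computes coupling coefficients `c_ij = softmax(b_ij)`, the weighted sum
`s_j = Σ_i c_ij û_{j|i}`, the squashed output

    v_j = (‖s_j‖² / (1 + ‖s_j‖²)) · s_j / ‖s_j‖ ,

and the agreement update `b_ij ← b_ij + û_{j|i} · v_j`.  Each output
capsule is a 16-dimensional vector whose norm (bounded in [0, 1)) reads
as the activity of a learned gene program and whose direction encodes
its state.  The coupling coefficients are recomputed on every forward
pass and excluded from the trainable parameter set; gradients reach the
votes only through the final weighted sum.  The softmax axis is
configurable: the default normalizes over input capsules `i` (the form
the coupling coefficient is usually printed in for this architecture);
`output_capsules` gives the original routing-by-agreement convention.
Three iterations are the default because more iterations concentrate
the couplings without improving discrimination.

**Attention decoder.** The 20 capsules form a length-20 sequence of
16-dim tokens.  Each of `H = 4` heads applies full-width projections
`Q = W_q V′`, `K = W_k V′`, `V = W_v V′` (each `d_c × d_c`) and scaled
dot-product attention `softmax(QKᵀ/√d_k) V` with `d_k = 16`.  Head
outputs are concatenated and flattened (head-major, row-major within a
head) into a 1280-dim feature vector.  There is no positional encoding,
feed-forward block or layer norm: capsules are an unordered set mixed
purely by learned relevance.

**Dense head.** One hidden layer of 150 neurons (sigmoid by default;
relu/tanh available for the activation sweep) followed by a single
logistic output unit.  The hidden-plus-output reading of "a dense layer
with 150 neurons and a sigmoid" was chosen over a single 150-unit layer
feeding sigmoid directly; both are supported by the architecture
description and the former is the conventional construction.

## Training

Binary cross-entropy `L = −(1/N) Σ [y log p + (1−y) log(1−p)]` with
probabilities clamped at 1e-7 from each boundary, minimized by Adam
(lr 1e-3, β = (0.9, 0.999), ε = 1e-8) on shuffled mini-batches of 32
for up to 50 epochs with early stopping (patience 5 on validation loss,
best weights restored).  Data are split 80/10/10 by cell under a seed;
a subject-stratified splitter is available for leakage-sensitive use.
Weights initialize fan-in uniform under the run seed; identical
seed/config/data reproduce the checkpoint exactly (fixed reduction
order, float64 throughout).

The network is trained by a compact tape-based reverse-mode autodiff
engine over NumPy (`genecaps.autodiff`), written for this package: the
model needs only dense linear algebra, broadcasting, softmax and
elementwise nonlinearities, and float64 reproducibility on a single CPU
was a design goal.  Because routing coefficients are
stop-gradients, the finite-difference gradient of the full loss is only
mathematically equal to the backprop gradient when the coefficients are
constants; the gradient check therefore runs at one routing iteration
(couplings are then the uniform softmax of zeros, independent of the
weights), which exercises every layer of the backward pass.

## Transfer to bulk cohorts

The pretrained single-cell model transfers to a bulk cohort in two
phases: the dense head is re-initialized and trained alone with the
encoder and attention frozen (exactly zero update, asserted bitwise),
then the entire network is fine-tuned at a lower learning rate.
Defaults are 50 epochs at 3e-3 (head) then 100 epochs at 3e-4 (full).
These are larger epoch counts than a single-cell run because a bulk
cohort of ~80 subjects yields only ~3 optimizer steps per epoch; the
counts were set so each phase performs a few hundred updates.
`fine_tune_fraction` (default 0.3, stratified by label) reproduces the
protocol of tuning on 30% of a bulk RNA-seq cohort and testing on the
rest; whole-cohort tuning (`fraction = 1.0`) reproduces the integrated
microarray protocol.  Phase 2 uses a fresh optimizer (no state carries
over from phase 1).  The rotated test fine-tunes on each cohort in turn
and evaluates on every other cohort, emitting the full n·(n−1) table.

## Interpretability

*Gene weights:* the importance of gene g for primary capsule i
aggregates column g of `W_i` — Euclidean norm over the `d_p` rows by
default (`mean_abs` and `signed_mean` reproduce sign-based displays).
Genes with aggregated importance above 0.06 in absolute value (strict
inequality) are "important" per capsule, with upset-style cross-capsule
intersection counts.

*Capsule activation test:* occlusion attribution by enumeration.  For
every gene, set it to a baseline (0 on the log scale by default, i.e.
"not detected"; optionally the reference mean) and record the mean
change of each output capsule's norm over reference samples; positive
scores mark activating genes.  The complementary `activate_single` mode
starts from an all-baseline input and re-activates one gene at a time.
Single-gene enumeration is the default; combinatorial subset activation
is out of scope.

*Enrichment:* upper-tail hypergeometric test P[X ≥ k] of a gene set
against any user-supplied GMT collection (population = the model's gene
universe), Benjamini–Hochberg corrected across the collection per
capsule.  No ontology is bundled; tests and the demo pipeline use the
GMT built from the generator's planted modules.  The capsule–pathway
network keeps the (capsule, set) pairs significant at α = 0.05.

## Metrics

AUROC is the rank statistic (Mann–Whitney with half-weight ties), which
equals trapezoidal integration of the all-thresholds ROC; positives are
predicted at score ≥ threshold.  AUPRC uses step-wise interpolation
(average precision) — linear PR interpolation is optimistic and
deliberately avoided.  Both error out rather than silently returning a
value when a class is absent.

## Synthetic test bed

The generator emulates a PBMC-like case/control study on the log2
scale directly (Gaussian baseline N(2, 1) clipped at 0) rather than at
count level, because every consumer operates on log-normalized values.
Defaults: 600 genes, 3 cell types, six disjoint 30-gene modules —
three cell-type markers (+1.5 in their type) and three disease modules
(+1.0 in case cells of every type, i.e. a systemic response; a
cell-type-restricted mode exists and is markedly harder to learn) —
40 case + 40 control subjects, 50 cells each, dropout 0.3 (single-cell
only).

Bulk cohorts average each subject's pre-dropout cells and then apply
four platform/population effects that create the single-cell → bulk
domain gap the transfer protocol exists to bridge: a cohort-level
affine shift (base scale 0.7, offset 3.0, ±25% across cohorts) with
per-gene probe jitter (±40%), Gaussian measurement noise (sd 0.3),
per-gene subject-level variation (sd 0.5), a per-case-subject severity
offset shared across disease genes (sd 1.5), and a case cell-type
composition tilt toward type 0 (whole-blood-like).  The severity spread
caps what any fixed scoring of disease genes can achieve, while the
composition channel is informative only in bulk — so a zero-shot
single-cell model is genuinely degraded and fine-tuning genuinely
recovers, mirroring the real platform gap.  Setting the four bulk
fields to zero recovers the pure affine `a·x + b` cohort.

What the generator does **not** model: count-level noise (library size,
UMI), doublets, batch chemistry, gene–gene correlation beyond module
structure, and any real biology.  Passing tests therefore demonstrate
that the architecture, optimization, transfer protocol and attribution
machinery behave as specified — not that the model attains any
particular accuracy on real sepsis cohorts.

## Problem sizes and numerical choices

Desk-scale runs use the default 4 000-cell single-cell cohort trained
for 15 epochs (a few seconds per epoch on one CPU) and 80-subject bulk
cohorts; the published-scale 50-epoch budget is the config default.
Squash guards the zero vector with a 1e-8 epsilon in the norm
denominator.  Probabilities are clamped at 1e-12 inside the classifier
(float saturation) and 1e-7 inside the loss.  Ties in AUROC use average
ranks.  Splits floor the validation/test sizes and give the remainder
to training.  Gene order after multi-matrix intersection is
lexicographic; checkpoints carry their own gene list, so any consistent
order round-trips.

## Known limitations

Routing with softmax over input capsules (the default, following the
printed coupling definition) means each *column* of c is a simplex over
inputs; the original convention (over outputs) is one config switch
away but changes learned representations.  The autodiff engine builds
one graph per batch in Python and is not suited to large models.  The
capsule–pathway network tests each capsule's gene set independently;
correlated capsules produce correlated edges.
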