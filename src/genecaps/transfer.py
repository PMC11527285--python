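"""Single-cell -> bulk transfer protocol and the rotated cross-cohort test.

Transfer re-initializes the dense classification head, trains it with
the capsule encoder and attention layers frozen (phase 1), then
unfreezes everything and fine-tunes the whole network at a smaller
learning rate (phase 2).  The rotated test fine-tunes on each cohort in
turn and evaluates on every other cohort.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .attention import ClassifierHeadParams
from .autodiff import Adam, no_grad
from .evaluation import auprc, auroc
from .expression_io import (LabelledDataset, ValidationError,
                            stratified_subset)
from .training import (ModelCheckpoint, TrainConfig, _aligned_batch,
                       bce_loss, forward, predict)


@dataclasses.dataclass
class TransferConfig:
    """Two-phase fine-tuning settings.

    Phase 1 trains the re-initialized head only (encoder and attention
    frozen); phase 2 trains every parameter, by default 10x slower to
    protect the pretrained features.  ``fine_tune_fraction`` is the
    label-stratified share of a target cohort used for tuning.
    """

    phase1_epochs: int = 50
    phase2_epochs: int = 100
    phase1_lr: float = 3e-3
    phase2_lr: float = 3e-4
    head_reinit_seed: int = 0
    fine_tune_fraction: float = 0.3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.phase1_epochs < 0 or self.phase2_epochs < 0:
            raise ValidationError("phase epochs must be >= 0")
        if self.phase1_epochs == 0 and self.phase2_epochs == 0:
            raise ValidationError("at least one phase must run")
        if not 0 < self.fine_tune_fraction <= 1:
            raise ValidationError("fine_tune_fraction must be in (0, 1]")


def reinit_head(ckpt: ModelCheckpoint, seed: int) -> ModelCheckpoint:
    """Re-draw the dense head; encoder/attention tensors are bit-identical
    copies of the input checkpoint."""
    out = ckpt.copy()
    rng = np.random.default_rng(seed)
    out.head = ClassifierHeadParams.initialize(
        rng, n_inputs=out.head.n_inputs,
        n_hidden=out.head.hidden_weights.shape[0])
    out.provenance = {**ckpt.provenance, "head_reinit_seed": int(seed)}
    return out


def _run_epochs(ckpt: ModelCheckpoint, X: np.ndarray, y: np.ndarray,
                params, lr: float, epochs: int, batch_size: int,
                rng: np.random.Generator) -> list[float]:
    """One fine-tuning phase; restores the best-loss weights at the end.

    Tiny cohorts make per-epoch losses noisy and an aggressive step can
    leave the last epoch worse than an earlier one, so the phase keeps a
    snapshot of the updated tensors at their lowest full-data loss.
    """
    losses = []
    opt = Adam(params, lr=lr)
    n = X.shape[0]
    yf = y.astype(np.float64)
    best_loss = np.inf
    best_state = None
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            p = forward(ckpt, X[idx])
            loss = bce_loss(yf[idx], p)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * idx.size
        losses.append(total / n)
        with no_grad():
            full_loss = bce_loss(yf, forward(ckpt, X).data)
        if full_loss < best_loss:
            best_loss = full_loss
            best_state = [t.data.copy() for t in params]
    if best_state is not None:
        for t, data in zip(params, best_state):
            t.data = data
    return losses


def fine_tune(ckpt: ModelCheckpoint, target: LabelledDataset,
              config: TransferConfig,
              reinit: bool = True) -> ModelCheckpoint:
    """Two-phase transfer onto a bulk target dataset.

    A stratified ``fine_tune_fraction`` of the target is used as tuning
    data.  Phase 1 updates only the (optionally re-initialized) head —
    the recorded ``phase1_frozen_max_change`` is exactly 0 for the other
    tensors.  Phase 2 trains the entire network with a fresh optimizer.
    """
    if len(np.unique(target.labels)) < 2:
        raise ValidationError("target cohort has a single class")
    tuned = reinit_head(ckpt, config.head_reinit_seed) if reinit \
        else ckpt.copy()
    if config.fine_tune_fraction < 1:
        tune_ds, _ = stratified_subset(target, config.fine_tune_fraction,
                                       config.seed)
    else:
        tune_ds = target
    X = _aligned_batch(tune_ds, tuned.gene_ids)
    y = tune_ds.labels
    rng = np.random.default_rng(config.seed)
    frozen_before = [t.data.copy() for t in
                     tuned.encoder.tensors() + tuned.attention.tensors()]
    phase1 = _run_epochs(tuned, X, y, tuned.head.tensors(),
                         config.phase1_lr, config.phase1_epochs,
                         config.batch_size, rng)
    frozen_change = max(
        (float(np.abs(t.data - before).max()) for t, before in
         zip(tuned.encoder.tensors() + tuned.attention.tensors(),
             frozen_before)), default=0.0)
    phase2 = _run_epochs(tuned, X, y, tuned.tensors(),
                         config.phase2_lr, config.phase2_epochs,
                         config.batch_size, rng)
    tuned.history = {"phase1_loss": phase1, "phase2_loss": phase2,
                     "phase1_frozen_max_change": frozen_change}
    tuned.provenance = {**tuned.provenance,
                        "transfer_seed": int(config.seed),
                        "n_tune": int(X.shape[0])}
    return tuned


def evaluate_on(ckpt: ModelCheckpoint, cohort: LabelledDataset
                ) -> dict[str, float]:
    p = predict(ckpt, cohort.matrix)
    return {"auroc": auroc(p, cohort.labels),
            "auprc": auprc(p, cohort.labels)}


def rotated_test(ckpt: ModelCheckpoint,
                 cohorts: Mapping[str, LabelledDataset],
                 config: Optional[TransferConfig] = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fine-tune on each cohort, evaluate on every other cohort.

    Returns ``(long, matrix)``: a long-format table with one row per
    (tuning cohort, test cohort) ordered pair — n*(n-1) rows when all
    cohorts are usable — and an AUROC pivot with NaN on the diagonal.
    Single-class cohorts are skipped as tuning targets, with a warning
    row recorded.
    """
    if len(cohorts) < 2:
        raise ValidationError("rotated test needs at least two cohorts")
    config = config or TransferConfig()
    rows = []
    for tune_name, tune_ds in cohorts.items():
        if len(np.unique(tune_ds.labels)) < 2:
            rows.append({"tune_cohort": tune_name, "test_cohort": None,
                         "auroc": np.nan, "auprc": np.nan,
                         "warning": "single-class cohort skipped"})
            continue
        tuned = fine_tune(ckpt, tune_ds, config)
        for test_name, test_ds in cohorts.items():
            if test_name == tune_name:
                continue
            if len(np.unique(test_ds.labels)) < 2:
                rows.append({"tune_cohort": tune_name,
                             "test_cohort": test_name,
                             "auroc": np.nan, "auprc": np.nan,
                             "warning": "single-class test cohort"})
                continue
            metrics = evaluate_on(tuned, test_ds)
            rows.append({"tune_cohort": tune_name, "test_cohort": test_name,
                         **metrics, "warning": ""})
    long = pd.DataFrame(rows)
    ok = long[long["test_cohort"].notna()]
    matrix = ok.pivot(index="tune_cohort", columns="test_cohort",
                      values="auroc")
    return long, matrix
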