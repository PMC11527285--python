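"""End-to-end training of the capsule encoder + attention classifier.

The model is trained with binary cross-entropy and Adam on shuffled
mini-batches, with early stopping on validation loss (best weights
restored).  Checkpoints bundle every parameter tensor with the gene
list, configuration and per-epoch history, and serialize to a directory
of ``.npy`` files plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .attention import (AttentionParams, ClassifierHeadParams, classify,
                        multi_head)
from .autodiff import Adam, Tensor, no_grad
from .capsule import CapsuleEncoderParams, encode
from .evaluation import auprc, auroc
from .expression_io import (ExpressionMatrix, LabelledDataset,
                            ValidationError)

PROB_CLAMP = 1e-7


@dataclasses.dataclass
class TrainConfig:
    """Optimization and architecture settings.

    Reference defaults: 50 epochs, batch 32, Adam at 1e-3, 3 routing
    iterations, sigmoid hidden activation, 8 primary capsules, 20 output
    capsules of 16 dims, 4 attention heads, 150 hidden neurons.
    """

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_patience: int = 5
    routing_iterations: int = 3
    seed: int = 0
    activation: str = "sigmoid"
    softmax_axis: str = "input_capsules"
    n_primary: int = 8
    n_capsules: int = 20
    d_primary: int = 16
    d_capsule: int = 16
    n_heads: int = 4
    n_hidden: int = 150
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.early_stopping_patience < 1:
            raise ValidationError("early_stopping_patience must be >= 1")
        if self.routing_iterations < 1:
            raise ValidationError("routing_iterations must be >= 1")

    def replace(self, **kw) -> "TrainConfig":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class ModelCheckpoint:
    """Trained parameters bound to a gene list, config and history."""

    encoder: CapsuleEncoderParams
    attention: AttentionParams
    head: ClassifierHeadParams
    gene_ids: list[str]
    config: TrainConfig
    history: dict[str, list]
    provenance: dict

    def tensors(self) -> list[Tensor]:
        return (self.encoder.tensors() + self.attention.tensors()
                + self.head.tensors())

    def copy(self) -> "ModelCheckpoint":
        return ModelCheckpoint(self.encoder.copy(), self.attention.copy(),
                               self.head.copy(), list(self.gene_ids),
                               self.config,
                               {k: list(v) for k, v in self.history.items()},
                               dict(self.provenance))

    # -- serialization ------------------------------------------------------

    _TENSOR_NAMES = ("primary_weights", "routing_weights", "W_q", "W_k",
                     "W_v", "hidden_weights", "hidden_bias",
                     "output_weights", "output_bias")

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        named = dict(zip(self._TENSOR_NAMES, self.tensors()))
        manifest = {
            "tensors": {n: list(t.shape) for n, t in named.items()},
            "d_k": self.attention.d_k,
            "config": dataclasses.asdict(self.config),
            "gene_ids": self.gene_ids,
            "history": self.history,
            "provenance": self.provenance,
        }
        for name, t in named.items():
            np.save(directory / f"{name}.npy", t.data)
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ModelCheckpoint":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        t = {name: Tensor(np.load(directory / f"{name}.npy"),
                          requires_grad=True)
             for name in cls._TENSOR_NAMES}
        cfg_dict = manifest["config"]
        cfg_dict["adam_betas"] = tuple(cfg_dict["adam_betas"])
        return cls(
            encoder=CapsuleEncoderParams(t["primary_weights"],
                                         t["routing_weights"]),
            attention=AttentionParams(t["W_q"], t["W_k"], t["W_v"],
                                      d_k=manifest["d_k"]),
            head=ClassifierHeadParams(t["hidden_weights"], t["hidden_bias"],
                                      t["output_weights"], t["output_bias"]),
            gene_ids=list(manifest["gene_ids"]),
            config=TrainConfig(**cfg_dict),
            history=manifest["history"],
            provenance=manifest["provenance"])


def initialize_model(gene_ids: Sequence[str], config: TrainConfig,
                     seed: Optional[int] = None) -> ModelCheckpoint:
    """Seeded fan-in uniform initialization of all three blocks."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    enc = CapsuleEncoderParams.initialize(
        len(gene_ids), rng, n_primary=config.n_primary,
        n_capsules=config.n_capsules, d_primary=config.d_primary,
        d_capsule=config.d_capsule)
    att = AttentionParams.initialize(rng, d_c=config.d_capsule,
                                     n_heads=config.n_heads)
    head = ClassifierHeadParams.initialize(
        rng, n_inputs=config.n_capsules * config.d_capsule * config.n_heads,
        n_hidden=config.n_hidden)
    return ModelCheckpoint(enc, att, head, [str(g) for g in gene_ids],
                           config, history={}, provenance={})


def forward(ckpt: ModelCheckpoint, x: Union[np.ndarray, Tensor]) -> Tensor:
    """Probabilities for a (batch, n_genes) block of aligned samples."""
    v = encode(x, ckpt.encoder,
               n_iterations=ckpt.config.routing_iterations,
               softmax_axis=ckpt.config.softmax_axis)
    z = multi_head(v, ckpt.attention)
    return classify(z, ckpt.head, activation=ckpt.config.activation)


def bce_loss(y: Union[np.ndarray, Sequence[float]],
             p: Union[np.ndarray, Tensor]) -> Union[float, Tensor]:
    """Mean binary cross-entropy, probabilities clamped at 1e-7.

    ``L = -(1/N) sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)]``
    """
    y_arr = np.asarray(y, dtype=np.float64)
    if isinstance(p, Tensor):
        if y_arr.shape != p.shape:
            raise ValidationError(f"labels {y_arr.shape} vs probabilities "
                                  f"{p.shape}")
        pc = p.clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
        yt = Tensor(y_arr)
        return -(yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()).mean()
    p_arr = np.asarray(p, dtype=np.float64)
    if y_arr.shape != p_arr.shape:
        raise ValidationError(f"labels {y_arr.shape} vs probabilities "
                              f"{p_arr.shape}")
    pc = np.clip(p_arr, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return float(-np.mean(y_arr * np.log(pc)
                          + (1.0 - y_arr) * np.log(1.0 - pc)))


def _aligned_batch(d: LabelledDataset, gene_ids: Sequence[str]) -> np.ndarray:
    """Samples x genes array in checkpoint gene order."""
    if list(d.matrix.gene_ids) == list(gene_ids):
        return np.ascontiguousarray(d.matrix.values.T)
    return np.ascontiguousarray(d.matrix.subset_genes(gene_ids).values.T)


def train(train_ds: LabelledDataset, val_ds: LabelledDataset,
          config: TrainConfig,
          init: Optional[ModelCheckpoint] = None) -> ModelCheckpoint:
    """Fit the full model; early-stop on validation loss, restore best.

    With the same data, config and seed the returned checkpoint is
    identical (the forward pass uses a fixed reduction order).
    """
    classes = set(np.unique(train_ds.labels))
    if classes != {0, 1}:
        raise ValidationError(f"training labels must contain both classes, "
                              f"got {sorted(classes)}")
    ckpt = (init.copy() if init is not None
            else initialize_model(train_ds.matrix.gene_ids, config))
    X_tr = _aligned_batch(train_ds, ckpt.gene_ids)
    X_va = _aligned_batch(val_ds, ckpt.gene_ids)
    y_tr = train_ds.labels.astype(np.float64)
    y_va = val_ds.labels.astype(np.float64)

    rng = np.random.default_rng(config.seed)
    opt = Adam(ckpt.tensors(), lr=config.learning_rate,
               betas=config.adam_betas, eps=config.adam_eps)
    history: dict[str, list] = {"epoch": [], "train_loss": [],
                                "val_loss": [], "val_auroc": []}
    best_loss = np.inf
    best_state = [t.data.copy() for t in ckpt.tensors()]
    best_epoch = 0
    stall = 0
    n = X_tr.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            p = forward(ckpt, X_tr[idx])
            loss = bce_loss(y_tr[idx], p)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, "
                    f"batch {start // config.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
        with no_grad():
            p_va = forward(ckpt, X_va).data
        val_loss = bce_loss(y_va, p_va)
        both = len(np.unique(y_va)) == 2
        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        history["val_auroc"].append(auroc(p_va, y_va) if both else np.nan)
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = [t.data.copy() for t in ckpt.tensors()]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stopping_patience:
                break
    for t, data in zip(ckpt.tensors(), best_state):
        t.data = data
    ckpt.history = history
    ckpt.provenance = {"seed": config.seed, "n_train": int(n),
                       "best_epoch": int(best_epoch),
                       "best_val_loss": float(best_loss)}
    return ckpt


def predict(ckpt: ModelCheckpoint, X: ExpressionMatrix) -> np.ndarray:
    """Per-sample probabilities; genes reordered to the checkpoint list."""
    aligned = X if list(X.gene_ids) == ckpt.gene_ids \
        else X.subset_genes(ckpt.gene_ids)
    with no_grad():
        return forward(ckpt, np.ascontiguousarray(aligned.values.T)).data


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Class-balanced disjoint folds covering every sample."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    out = [np.sort(np.array(f, dtype=int)) for f in folds]
    for f in out:
        if len(np.unique(labels[f])) < 2:
            raise ValidationError("a fold lost one class; use smaller k")
    return out


def crossvalidate(d: LabelledDataset, config: TrainConfig,
                  grid: Optional[dict[str, list]] = None,
                  k: int = 5) -> pd.DataFrame:
    """Stratified k-fold sweep over a hyperparameter grid.

    ``grid`` maps TrainConfig field names (e.g. ``n_capsules``,
    ``n_hidden``, ``routing_iterations``, ``activation``) to candidate
    values; the Cartesian product is evaluated.  Returns one row per
    (grid point, fold) with AUROC/AUPRC on the held-out fold.
    """
    import itertools

    grid = grid or {}
    keys = sorted(grid)
    folds = stratified_folds(d.labels, k, config.seed)
    all_idx = np.arange(d.n_samples)
    rows = []
    combos = list(itertools.product(*(grid[key] for key in keys))) or [()]
    for combo in combos:
        overrides = dict(zip(keys, combo))
        cfg = config.replace(**overrides)
        for fold_i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            tr = d.subset(train_idx)
            te = d.subset(test_idx)
            ckpt = train(tr, te, cfg)
            p = predict(ckpt, te.matrix)
            rows.append({**overrides, "fold": fold_i,
                         "auroc": auroc(p, te.labels),
                         "auprc": auprc(p, te.labels)})
    return pd.DataFrame(rows)
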