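"""Reading, validation, filtering and normalization of expression matrices.

The in-memory contract is :class:`ExpressionMatrix`: an ordered
genes x samples array of finite, non-negative log-scale values with
unique gene and sample identifiers.  Dense TSV/CSV (header = sample ids,
first column = gene ids) and MatrixMarket coordinate files with
``genes.tsv``/``barcodes.tsv`` sidecars are supported, plus GMT gene-set
collections and two-column label tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Input violates a documented contract (shapes, ranges, uniqueness)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


PlatformTag = Literal["single_cell", "bulk_rnaseq", "microarray", "synthetic"]


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with ordered identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform_tag: PlatformTag = "synthetic"
    normalization_tag: str = ""

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values contain NaN or Inf")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(
                f"{len(missing)} gene(s) absent from matrix; first 10: "
                f"{missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[rows], self.platform_tag,
                                self.normalization_tag)

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(list(self.gene_ids),
                                [self.sample_ids[i] for i in idx],
                                self.values[:, idx], self.platform_tag,
                                self.normalization_tag)


@dataclasses.dataclass
class LabelledDataset:
    """An expression matrix with per-sample binary case/control labels."""

    matrix: ExpressionMatrix
    labels: np.ndarray
    cell_type: Optional[list[str]] = None
    subject_id: Optional[list[str]] = None
    cohort_id: Optional[list[str]] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.matrix.n_samples,):
            raise ValidationError(
                f"label length {self.labels.shape} != number of samples "
                f"({self.matrix.n_samples})")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValidationError("labels must be 0 (control) or 1 (case)")
        self.labels = self.labels.astype(np.int64)
        for name in ("cell_type", "subject_id", "cohort_id"):
            val = getattr(self, name)
            if val is not None and len(val) != self.matrix.n_samples:
                raise ValidationError(f"{name} length != number of samples")

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    def subset(self, idx: Sequence[int]) -> "LabelledDataset":
        idx = list(idx)

        def pick(v):
            return None if v is None else [v[i] for i in idx]

        return LabelledDataset(self.matrix.subset_samples(idx),
                               self.labels[idx], pick(self.cell_type),
                               pick(self.subject_id), pick(self.cohort_id))


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO biological-process exports in GMT form)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def restricted_to(self, universe: Sequence[str]) -> "GeneSetCollection":
        uni = set(universe)
        kept = {name: [g for g in genes if g in uni]
                for name, genes in self.sets.items()}
        return GeneSetCollection({n: g for n, g in kept.items() if g},
                                 source=self.source)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, format: str = "tsv",
                    orientation: str = "genes_by_samples",
                    platform_tag: PlatformTag = "synthetic",
                    genes_path=None, barcodes_path=None) -> ExpressionMatrix:
    """Read a dense TSV/CSV or a MatrixMarket triplet file.

    ``orientation`` names the layout *on disk*; the returned matrix is
    always genes x samples.  MTX input needs ``genes.tsv``/``barcodes.tsv``
    sidecars next to the matrix file (or explicit paths).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        return _read_mtx(path, genes_path, barcodes_path, platform_tag)
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    vals = df.to_numpy()
    if vals.dtype.kind not in "fiu":
        bad = df.columns[[d.kind not in "fiu" for d in df.dtypes]][0]
        raise ParseError(f"{path}: non-numeric column {bad!r}")
    return ExpressionMatrix([str(i) for i in df.index],
                            [str(c) for c in df.columns], vals,
                            platform_tag=platform_tag)


def _read_mtx(path: Path, genes_path, barcodes_path,
              platform_tag: PlatformTag) -> ExpressionMatrix:
    genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
    barcodes_path = (Path(barcodes_path) if barcodes_path
                     else path.parent / "barcodes.tsv")
    for p in (genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(f"MTX sidecar missing: {p}")
    try:
        mat = scipy.io.mmread(str(path))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    genes = [ln.split("\t")[0].strip() for ln in
             genes_path.read_text().splitlines() if ln.strip()]
    barcodes = [ln.split("\t")[0].strip() for ln in
                barcodes_path.read_text().splitlines() if ln.strip()]
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                       dtype=np.float64)
    return ExpressionMatrix(genes, barcodes, dense, platform_tag=platform_tag)


def write_expression(m: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write a dense matrix with 12-significant-digit formatting."""
    sep = "\t" if format == "tsv" else ","
    m.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def read_labels(path, sample_ids: Sequence[str],
                label_column: str = "label") -> np.ndarray:
    """Read a two-plus-column TSV keyed by sample id; align to ``sample_ids``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if label_column not in df.columns:
        raise ParseError(f"{path}: missing column {label_column!r}")
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} sample(s) absent from label table; first 10: "
            f"{missing[:10]}")
    return df.loc[list(sample_ids), label_column].to_numpy()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate genes within a set are collapsed; duplicate set names are an
    error.  Descriptions are folded into the ``source`` metadata.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 "
                             f"tab-separated fields, got {len(fields)}")
        name = fields[0]
        if name in sets:
            raise ParseError(f"{path}: line {lineno}: duplicate set name "
                             f"{name!r}")
        seen: set[str] = set()
        genes = []
        for g in fields[2:]:
            g = g.strip()
            if g and g not in seen:
                seen.add(g)
                genes.append(g)
        sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes)
             for name, genes in collection.sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# filtering / normalization / alignment
# ---------------------------------------------------------------------------

def filter_matrix(m: ExpressionMatrix, min_gene_fraction: float = 0.20,
                  min_cell_fraction: float = 0.20) -> ExpressionMatrix:
    """Drop sparse samples, then sparse genes.

    A sample is kept when at least ``min_gene_fraction`` of genes have a
    strictly positive value in it; afterwards a gene is kept when at least
    ``min_cell_fraction`` of the *retained* samples record it.  Zero on the
    log scale is treated as "not detected".  Order is preserved.
    """
    detected = m.values > 0
    sample_frac = detected.mean(axis=0)
    keep_samples = np.flatnonzero(sample_frac >= min_gene_fraction)
    if keep_samples.size == 0:
        raise ValidationError("filter removed every sample")
    gene_frac = detected[:, keep_samples].mean(axis=1)
    keep_genes = np.flatnonzero(gene_frac >= min_cell_fraction)
    if keep_genes.size == 0:
        raise ValidationError("filter removed every gene")
    return ExpressionMatrix([m.gene_ids[i] for i in keep_genes],
                            [m.sample_ids[j] for j in keep_samples],
                            m.values[np.ix_(keep_genes, keep_samples)],
                            m.platform_tag, m.normalization_tag)


def log_normalize(m: ExpressionMatrix,
                  gene_lengths: Optional[Mapping[str, float]] = None,
                  mode: str = "log2_cpm") -> ExpressionMatrix:
    """Library-size normalize counts and apply log2(x + 1).

    ``log2_tpm`` divides counts by gene length in kilobases before scaling
    each sample to one million; ``log2_cpm`` skips the length step;
    ``passthrough`` asserts the matrix is already log scale (finite,
    non-negative) and only tags it.
    """
    if mode == "passthrough":
        if np.any(m.values < 0):
            raise ValidationError("passthrough requires non-negative "
                                  "(already log-scale) values")
        return dataclasses.replace(m, normalization_tag="passthrough")
    if np.any(m.values < 0):
        raise ValidationError("counts must be non-negative")
    rates = m.values.astype(np.float64)
    if mode == "log2_tpm":
        if gene_lengths is None:
            raise ValidationError("log2_tpm requires gene_lengths")
        lengths = np.empty(m.n_genes)
        for i, g in enumerate(m.gene_ids):
            if g not in gene_lengths:
                raise ValidationError(f"missing gene length for {g!r}")
            if gene_lengths[g] <= 0:
                raise ValidationError(f"non-positive length for gene {g!r}")
            lengths[i] = gene_lengths[g]
        rates = rates / (lengths[:, None] / 1000.0)
    elif mode != "log2_cpm":
        raise ValueError(f"unknown mode {mode!r}")
    totals = rates.sum(axis=0)
    scaled = np.divide(rates * 1e6, totals, out=np.zeros_like(rates),
                       where=totals > 0)
    return dataclasses.replace(m, values=np.log2(scaled + 1.0),
                               normalization_tag=mode)


def intersect_genes(matrices: Sequence[ExpressionMatrix]
                    ) -> list[ExpressionMatrix]:
    """Restrict all matrices to the shared gene set, lexicographic order."""
    if len(matrices) < 2:
        raise ValidationError("need at least two matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValidationError("gene intersection is empty")
    order = sorted(common)
    return [m.subset_genes(order) for m in matrices]


def split_cells(d: LabelledDataset,
                fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                seed: int = 0) -> tuple[LabelledDataset, LabelledDataset,
                                        LabelledDataset]:
    """Uniform random train/val/test partition of samples.

    Validation and test sizes are floored; the remainder goes to training.
    The same seed always yields the same membership.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must be positive and sum to 1")
    n = d.n_samples
    n_val = int(np.floor(f_val * n))
    n_test = int(np.floor(f_test * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValidationError(
            f"split of {n} samples with fractions {fractions} leaves an "
            "empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    tr = np.sort(perm[:n_train])
    va = np.sort(perm[n_train:n_train + n_val])
    te = np.sort(perm[n_train + n_val:])
    return d.subset(tr), d.subset(va), d.subset(te)


def stratified_subset(d: LabelledDataset, fraction: float, seed: int
                      ) -> tuple[LabelledDataset, LabelledDataset]:
    """Label-stratified (selected, remainder) split; at least one per class."""
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(d.labels == cls)
        if idx.size == 0:
            raise ValidationError(f"class {cls} absent from dataset")
        k = max(1, int(round(fraction * idx.size)))
        chosen.extend(rng.choice(idx, size=min(k, idx.size), replace=False))
    chosen_sorted = sorted(chosen)
    rest = sorted(set(range(d.n_samples)) - set(chosen_sorted))
    return d.subset(chosen_sorted), d.subset(rest)
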