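"""Synthetic single-cell and bulk expression cohorts with planted modules.

Cells carry a cell type and a case/control label inherited from their
subject.  Expression is log-scale Gaussian around a baseline; disjoint
gene modules add structure: *marker* modules raise their genes in one
cell type, *disease* modules raise their genes by an effect size delta
in case cells of the affected cell types.  Single-cell output adds
zero-inflation (dropout); bulk cohorts average each subject's
pre-dropout cells and apply a cohort-specific affine platform shift with
measurement noise, emulating microarray/RNA-seq domain gaps.

The generator works on the log scale directly (Gaussian, clipped at 0)
rather than simulating counts, because every downstream consumer
operates on log-normalized values.  It does not model library-size
variation, UMI noise or doublets.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression_io import (ExpressionMatrix, GeneSetCollection,
                            LabelledDataset, ValidationError)


@dataclasses.dataclass
class ModuleSpec:
    """A block of co-regulated genes.

    ``kind='cell_type_marker'`` raises the module in cells of type
    ``cell_type`` by ``effect``; ``kind='disease'`` raises it by
    ``effect`` in case cells whose type is in ``affected_cell_types``.
    """

    name: str
    gene_indices: list[int]
    kind: str  # 'cell_type_marker' | 'disease'
    effect: float
    cell_type: Optional[int] = None
    affected_cell_types: Optional[list[int]] = None

    def __post_init__(self):
        if self.kind not in ("cell_type_marker", "disease"):
            raise ValidationError(f"unknown module kind {self.kind!r}")
        if self.kind == "cell_type_marker" and self.cell_type is None:
            raise ValidationError("marker module needs a cell_type")
        if self.kind == "disease" and not self.affected_cell_types:
            raise ValidationError("disease module needs affected_cell_types")
        if not np.isfinite(self.effect):
            raise ValidationError("module effect must be finite")


def default_modules(n_genes: int = 600, n_cell_types: int = 3,
                    module_size: int = 30, marker_effect: float = 1.5,
                    disease_effect: float = 1.0,
                    systemic_disease: bool = True) -> list[ModuleSpec]:
    """One marker module per cell type + as many disease modules, laid
    out in consecutive blocks from gene 0.

    By default disease modules are *systemic* — active in case cells of
    every type, like the broadly shared inflammatory response of sepsis
    in blood.  ``systemic_disease=False`` restricts disease module t to
    cell type t (a strictly harder, cell-type-conditional signal).
    """
    modules = []
    start = 0
    for t in range(n_cell_types):
        modules.append(ModuleSpec(
            name=f"marker_type{t}",
            gene_indices=list(range(start, start + module_size)),
            kind="cell_type_marker", effect=marker_effect, cell_type=t))
        start += module_size
    for t in range(n_cell_types):
        modules.append(ModuleSpec(
            name=f"disease_mod{t}",
            gene_indices=list(range(start, start + module_size)),
            kind="disease", effect=disease_effect,
            affected_cell_types=(list(range(n_cell_types))
                                 if systemic_disease else [t])))
        start += module_size
    if start > n_genes:
        raise ValidationError("modules exceed n_genes")
    return modules


@dataclasses.dataclass
class SyntheticSpec:
    """Generative parameters for a planted-module case/control study.

    Desk-scale defaults: 600 genes, 3 cell types, six disjoint 30-gene
    modules, baseline N(2, 1) on the log2 scale clipped at 0, dropout
    0.3 (single-cell only), 40 case + 40 control subjects with 50 cells
    each, and a bulk platform shift around scale 0.7 / offset 3.0 with
    noise sd 0.3.
    """

    n_genes: int = 600
    n_cell_types: int = 3
    modules: list[ModuleSpec] = dataclasses.field(
        default_factory=default_modules)
    baseline_mean: float = 2.0
    baseline_sd: float = 1.0
    dropout_rate: float = 0.3
    n_subjects_case: int = 40
    n_subjects_control: int = 40
    cells_per_subject: int = 50
    bulk_platform_shift: tuple[float, float, float] = (0.7, 3.0, 0.3)
    bulk_probe_jitter: float = 0.4
    bulk_severity_sd: float = 1.5
    bulk_subject_sd: float = 0.5
    bulk_composition_shift: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.cells_per_subject < 1:
            raise ValidationError("cells_per_subject must be >= 1")
        used: set[int] = set()
        for mod in self.modules:
            idx = set(mod.gene_indices)
            if idx & used:
                raise ValidationError(
                    f"module {mod.name!r} overlaps an earlier module")
            if max(idx, default=-1) >= self.n_genes or min(idx, default=0) < 0:
                raise ValidationError(
                    f"module {mod.name!r} indices out of range")
            used |= idx

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def disease_gene_indices(self) -> np.ndarray:
        idx = sorted(i for m in self.modules if m.kind == "disease"
                     for i in m.gene_indices)
        return np.asarray(idx, dtype=int)

    def module_table(self) -> pd.DataFrame:
        rows = []
        genes = self.gene_ids()
        for m in self.modules:
            for i in m.gene_indices:
                rows.append({"gene_id": genes[i], "module": m.name,
                             "kind": m.kind, "effect": m.effect})
        return pd.DataFrame(rows)


def _simulate_cells(spec: SyntheticSpec, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pre-dropout expression (cells x genes), label, cell type, subject."""
    n_subjects = spec.n_subjects_case + spec.n_subjects_control
    n_cells = n_subjects * spec.cells_per_subject
    subj = np.repeat(np.arange(n_subjects), spec.cells_per_subject)
    labels = (subj < spec.n_subjects_case).astype(np.int64)
    cell_type = rng.integers(0, spec.n_cell_types, size=n_cells)
    expr = rng.normal(spec.baseline_mean, spec.baseline_sd,
                      (n_cells, spec.n_genes))
    for m in spec.modules:
        cols = np.asarray(m.gene_indices, dtype=int)
        if m.kind == "cell_type_marker":
            rows = cell_type == m.cell_type
        else:
            rows = (labels == 1) & np.isin(cell_type, m.affected_cell_types)
        expr[np.ix_(rows, cols)] += m.effect
    np.clip(expr, 0.0, None, out=expr)
    return expr, labels, cell_type, subj


def generate_single_cell(spec: SyntheticSpec
                         ) -> tuple[LabelledDataset, pd.DataFrame]:
    """Simulate one single-cell cohort; returns (dataset, module table).

    Dropout zeroes each entry independently at ``spec.dropout_rate``.
    Identical spec + seed reproduce the dataset bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    expr, labels, cell_type, subj = _simulate_cells(spec, rng)
    if spec.dropout_rate > 0:
        mask = rng.random(expr.shape) < spec.dropout_rate
        expr = np.where(mask, 0.0, expr)
    n_cells = expr.shape[0]
    matrix = ExpressionMatrix(
        spec.gene_ids(), [f"cell{i:05d}" for i in range(n_cells)],
        expr.T, platform_tag="single_cell", normalization_tag="synthetic_log2")
    ds = LabelledDataset(matrix, labels,
                         cell_type=[f"type{t}" for t in cell_type],
                         subject_id=[f"subj{s:03d}" for s in subj])
    return ds, spec.module_table()


def _case_type_probs(spec: SyntheticSpec) -> np.ndarray:
    """Case subjects' cell-type mix, tilted toward type 0."""
    probs = np.full(spec.n_cell_types, 1.0 / spec.n_cell_types)
    probs[0] += spec.bulk_composition_shift
    return probs / probs.sum()


def generate_bulk(spec: SyntheticSpec, n_cohorts: int = 1,
                  shifts: Optional[Sequence[tuple[float, float, float]]]
                  = None) -> list[LabelledDataset]:
    """Simulate bulk cohorts (fresh subjects each) with platform shifts.

    Each subject's profile is the mean of its simulated cells *before*
    dropout (dropout is a single-cell measurement artifact).  Bulk
    differs from the single-cell cohort in four realistic ways beyond
    averaging:

    * **probe effects** — cohort c has a base affine shift (a_c, b_c)
      around the spec's ``bulk_platform_shift`` (+/-25% cohort jitter
      unless explicit ``shifts`` are given), and every gene draws its
      own scale/offset within ``bulk_probe_jitter`` relative spread of
      the cohort base, like probe-specific microarray response;
    * **severity spread** — each case subject adds a N(0, severity_sd)
      offset, shared across all disease-module genes, emulating the
      clinical severity spectrum of independent cohorts;
    * **composition shift** — case subjects draw their cells from a
      type mix tilted toward cell type 0 (``bulk_composition_shift``),
      as whole-blood composition shifts with disease, while controls
      stay uniform;
    * **subject noise** — per-gene biological/technical variation of sd
      ``bulk_subject_sd`` on top of the cell average.

    Gaussian measurement noise is added last and values clip at zero.
    Setting the four spec fields to zero reduces a cohort to exactly
    ``a * subject_means + b`` (+ noise).
    """
    if n_cohorts < 1:
        raise ValidationError("n_cohorts must be >= 1")
    base_a, base_b, noise_sd = spec.bulk_platform_shift
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    if shifts is not None:
        if len(shifts) != n_cohorts:
            raise ValidationError("need one (scale, offset, noise) per cohort")
        cohort_shifts = [tuple(map(float, s)) for s in shifts]
    else:
        cohort_shifts = [
            (base_a * rng.uniform(0.75, 1.25),
             base_b * rng.uniform(0.75, 1.25), noise_sd)
            for _ in range(n_cohorts)]
    n_subjects = spec.n_subjects_case + spec.n_subjects_control
    case_probs = _case_type_probs(spec)
    uniform_probs = np.full(spec.n_cell_types, 1.0 / spec.n_cell_types)
    disease_idx = spec.disease_gene_indices()
    cohorts = []
    for c, (a, b, sd) in enumerate(cohort_shifts):
        profiles = np.empty((n_subjects, spec.n_genes))
        subj_labels = (np.arange(n_subjects)
                       < spec.n_subjects_case).astype(np.int64)
        for s in range(n_subjects):
            is_case = subj_labels[s] == 1
            probs = case_probs if is_case else uniform_probs
            cell_type = rng.choice(spec.n_cell_types,
                                   size=spec.cells_per_subject, p=probs)
            expr = rng.normal(spec.baseline_mean, spec.baseline_sd,
                              (spec.cells_per_subject, spec.n_genes))
            for m in spec.modules:
                cols = np.asarray(m.gene_indices, dtype=int)
                if m.kind == "cell_type_marker":
                    rows = cell_type == m.cell_type
                else:
                    rows = (np.isin(cell_type, m.affected_cell_types)
                            if is_case else np.zeros_like(cell_type, bool))
                expr[np.ix_(rows, cols)] += m.effect
            np.clip(expr, 0.0, None, out=expr)
            profiles[s] = expr.mean(axis=0)
            if is_case and spec.bulk_severity_sd > 0 and disease_idx.size:
                profiles[s, disease_idx] += rng.normal(
                    0.0, spec.bulk_severity_sd)
        vals = profiles.T  # genes x subjects
        if spec.bulk_subject_sd > 0:
            vals = vals + rng.normal(0.0, spec.bulk_subject_sd, vals.shape)
        j = spec.bulk_probe_jitter
        a_g = rng.uniform(a * (1 - j), a * (1 + j),
                          spec.n_genes)[:, None] if j > 0 else a
        b_g = rng.uniform(b * (1 - j), b * (1 + j),
                          spec.n_genes)[:, None] if j > 0 else b
        vals = a_g * vals + b_g
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, vals.shape)
        np.clip(vals, 0.0, None, out=vals)
        name = f"cohort{c}"
        matrix = ExpressionMatrix(
            spec.gene_ids(),
            [f"{name}_subj{s:03d}" for s in range(n_subjects)],
            vals, platform_tag="bulk_rnaseq",
            normalization_tag="synthetic_log2")
        cohorts.append(LabelledDataset(
            matrix, subj_labels, cohort_id=[name] * n_subjects))
    return cohorts


def planted_gmt(spec: SyntheticSpec) -> GeneSetCollection:
    """The planted modules as a gene-set collection (toy GMT)."""
    genes = spec.gene_ids()
    return GeneSetCollection(
        {m.name: [genes[i] for i in m.gene_indices] for m in spec.modules},
        source="planted synthetic modules")
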