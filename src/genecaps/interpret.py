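"""Capsule interpretability: gene weights, occlusion tests, enrichment.

Three complementary views of what the network learned:

* **Primary-capsule gene weights** — each gene's contribution to primary
  capsule i, aggregated from column g of W_i; genes whose aggregated
  weight exceeds a threshold (default 0.06 in absolute value, strict
  inequality) are called "important" per capsule.
* **Capsule activation test** — occlusion attribution: set one gene at a
  time to a baseline and measure the mean change in an output capsule's
  norm over reference samples, enumerating every gene.  A positive score
  means the gene activates the capsule.
* **Gene-set enrichment** — upper-tail hypergeometric test of a gene set
  against a user-supplied collection (e.g. GO exports in GMT form) with
  Benjamini-Hochberg correction, and a capsule-pathway bipartite network
  built from the significant (capsule, set) pairs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .autodiff import no_grad
from .capsule import capsule_norms, encode
from .expression_io import (ExpressionMatrix, GeneSetCollection,
                            ValidationError)
from .training import ModelCheckpoint

AGGREGATIONS = ("l2_norm", "mean_abs", "signed_mean")
IMPORTANCE_THRESHOLD = 0.06


@dataclasses.dataclass
class GeneImportanceTable:
    """(n_genes x P) aggregated primary-capsule weights."""

    gene_ids: list[str]
    importance: np.ndarray
    aggregation_tag: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"primary_capsule_{i}"
                for i in range(self.importance.shape[1])]
        return pd.DataFrame(self.importance, index=self.gene_ids,
                            columns=cols)


@dataclasses.dataclass
class CapsuleAttribution:
    """Signed per-gene occlusion scores for one output capsule."""

    capsule_index: int
    gene_ids: list[str]
    scores: np.ndarray
    baseline_tag: str
    mode: str

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.gene_ids,
                         name=f"capsule_{self.capsule_index}")


def primary_capsule_gene_weights(params, aggregation: str = "l2_norm",
                                 gene_ids: Sequence[str] | None = None
                                 ) -> GeneImportanceTable:
    """Aggregate each W_i column into one scalar per (gene, primary capsule).

    ``l2_norm`` takes the Euclidean norm over the d_p rows; ``mean_abs``
    and ``signed_mean`` the mean of absolute / raw entries.
    """
    if aggregation not in AGGREGATIONS:
        raise ValidationError(f"aggregation must be one of {AGGREGATIONS}")
    W = params.primary_weights.data  # (P, d_p, n)
    if aggregation == "l2_norm":
        imp = np.linalg.norm(W, axis=1)
    elif aggregation == "mean_abs":
        imp = np.abs(W).mean(axis=1)
    else:
        imp = W.mean(axis=1)
    gene_ids = list(gene_ids) if gene_ids is not None \
        else [f"g{i}" for i in range(W.shape[2])]
    return GeneImportanceTable(gene_ids, imp.T, aggregation)


def important_genes(table: GeneImportanceTable,
                    threshold: float = IMPORTANCE_THRESHOLD
                    ) -> tuple[dict[int, list[str]], pd.Series]:
    """Per-capsule gene sets with |importance| strictly above threshold.

    Also returns cross-capsule intersection counts: for every observed
    combination of capsules, how many genes are selected by exactly that
    combination (upset-plot style).
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    selected = np.abs(table.importance) > threshold  # (n_genes, P)
    sets = {i: [g for g, keep in zip(table.gene_ids, selected[:, i]) if keep]
            for i in range(selected.shape[1])}
    combos: dict[tuple[int, ...], int] = {}
    for row in selected:
        combo = tuple(np.flatnonzero(row))
        if combo:
            combos[combo] = combos.get(combo, 0) + 1
    counts = pd.Series(
        {"+".join(map(str, k)): v for k, v in sorted(combos.items())},
        dtype=int, name="n_genes")
    return sets, counts


def _capsule_norm_matrix(ckpt: ModelCheckpoint, X: np.ndarray) -> np.ndarray:
    with no_grad():
        v = encode(X, ckpt.encoder,
                   n_iterations=ckpt.config.routing_iterations,
                   softmax_axis=ckpt.config.softmax_axis)
    return capsule_norms(v)  # (B, J)


def attribution_matrix(ckpt: ModelCheckpoint, reference: ExpressionMatrix,
                       mode: str = "occlude_single",
                       baseline: str = "zero") -> np.ndarray:
    """Occlusion scores for all genes x all capsules in one enumeration.

    Returns (n_genes, J).  ``occlude_single``: score[g, j] is the mean
    over reference samples of ||v_j||(x) - ||v_j||(x with gene g at
    baseline).  ``activate_single``: ||v_j||(baseline except g) -
    ||v_j||(baseline everywhere).
    """
    if mode not in ("occlude_single", "activate_single"):
        raise ValidationError(f"unknown mode {mode!r}")
    if baseline not in ("zero", "mean"):
        raise ValidationError(f"unknown baseline {baseline!r}")
    aligned = reference if list(reference.gene_ids) == ckpt.gene_ids \
        else reference.subset_genes(ckpt.gene_ids)
    X = np.ascontiguousarray(aligned.values.T)  # (B, n)
    base_vals = np.zeros(X.shape[1]) if baseline == "zero" \
        else X.mean(axis=0)
    n_genes = X.shape[1]
    scores = np.empty((n_genes, ckpt.config.n_capsules))
    if mode == "occlude_single":
        ref_norms = _capsule_norm_matrix(ckpt, X)  # (B, J)
        for g in range(n_genes):
            saved = X[:, g].copy()
            X[:, g] = base_vals[g]
            scores[g] = (ref_norms - _capsule_norm_matrix(ckpt, X)).mean(axis=0)
            X[:, g] = saved
    else:
        Xb = np.tile(base_vals, (X.shape[0], 1))
        base_norms = _capsule_norm_matrix(ckpt, Xb)
        for g in range(n_genes):
            saved = Xb[:, g].copy()
            Xb[:, g] = X[:, g]
            scores[g] = (_capsule_norm_matrix(ckpt, Xb)
                         - base_norms).mean(axis=0)
            Xb[:, g] = saved
    return scores


def capsule_activation_test(ckpt: ModelCheckpoint,
                            reference: ExpressionMatrix,
                            capsule_index: int,
                            mode: str = "occlude_single",
                            baseline: str = "zero") -> CapsuleAttribution:
    """Occlusion attribution of every gene to one output capsule."""
    if not 0 <= capsule_index < ckpt.config.n_capsules:
        raise ValidationError(
            f"capsule index {capsule_index} out of range "
            f"[0, {ckpt.config.n_capsules})")
    scores = attribution_matrix(ckpt, reference, mode=mode,
                                baseline=baseline)
    return CapsuleAttribution(capsule_index, list(ckpt.gene_ids),
                              scores[:, capsule_index], baseline, mode)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def hypergeometric_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not 0 <= k <= min(K, n) <= N:
        raise ValidationError(f"invalid hypergeometric instance "
                              f"(k={k}, N={N}, K={K}, n={n})")
    return float(min(scipy.stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def hypergeometric_enrichment(query: Sequence[str],
                              collection: GeneSetCollection,
                              universe: Sequence[str],
                              alpha: float = 0.05,
                              correction: str = "bh") -> pd.DataFrame:
    """Upper-tail hypergeometric P[X >= k] per set, multiplicity-corrected.

    Population N = |universe|, successes K = |set ∩ universe|, draws
    n = |query|, overlap k.  Rows are sorted by p-value; ``significant``
    flags adjusted_p < alpha.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValidationError("universe is empty")
    uni_set = set(uni)
    q = set(query)
    if not q <= uni_set:
        raise ValidationError("query genes must be a subset of the universe")
    N, n = len(uni_set), len(q)
    rows = []
    for name, genes in collection.sets.items():
        members = set(genes) & uni_set
        K = len(members)
        if K == 0:
            continue
        k = len(q & members)
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N,
                     "p_value": hypergeometric_pvalue(k, N, K, n)})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["set_name", "overlap", "set_size",
                                     "query_size", "universe_size",
                                     "p_value", "adjusted_p", "significant"])
    if correction == "bh":
        _, adj, _, _ = multipletests(df["p_value"], method="fdr_bh")
    elif correction == "bonferroni":
        adj = np.minimum(df["p_value"] * len(df), 1.0)
    elif correction == "none":
        adj = df["p_value"].to_numpy()
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    df["adjusted_p"] = adj
    df["significant"] = df["adjusted_p"] < alpha
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def capsule_pathway_network(attributions: Mapping[int, Sequence[str]],
                            collection: GeneSetCollection,
                            universe: Sequence[str],
                            alpha: float = 0.05
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bipartite capsule-pathway graph from per-capsule enrichments.

    An edge (capsule j, set S) is emitted iff S is significant for
    capsule j's gene set at BH-adjusted ``alpha``.  Returns
    (nodes, edges); an empty edge table is legitimate.
    """
    if not attributions:
        raise ValidationError("need gene sets for at least one capsule")
    edges = []
    pathway_nodes: set[str] = set()
    for j, genes in attributions.items():
        if not genes:
            continue
        enr = hypergeometric_enrichment(genes, collection, universe,
                                        alpha=alpha, correction="bh")
        for _, row in enr[enr["significant"]].iterrows():
            edges.append({"capsule": j, "pathway": row["set_name"],
                          "adjusted_p": row["adjusted_p"],
                          "overlap": row["overlap"]})
            pathway_nodes.add(row["set_name"])
    nodes = pd.DataFrame(
        [{"node": f"capsule_{j}", "type": "capsule"}
         for j in sorted(attributions)]
        + [{"node": s, "type": "pathway"} for s in sorted(pathway_nodes)])
    edge_df = pd.DataFrame(edges, columns=["capsule", "pathway",
                                           "adjusted_p", "overlap"])
    return nodes, edge_df


def module_recovery_auc(scores: np.ndarray, module_mask: np.ndarray) -> float:
    """Ranking AUC: do |scores| rank planted-module genes above background?"""
    from .evaluation import auroc
    return auroc(np.abs(scores), module_mask.astype(int))


def best_capsule_recovery(attr: np.ndarray, module_mask: np.ndarray
                          ) -> tuple[int, float]:
    """The capsule whose attribution best separates module genes, with
    its ranking AUC."""
    aucs = [module_recovery_auc(attr[:, j], module_mask)
            for j in range(attr.shape[1])]
    best = int(np.argmax(aucs))
    return best, float(aucs[best])
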