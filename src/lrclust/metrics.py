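"""Clustering evaluation against a reference partition.

Recall and precision are computed from the L×K contingency table R, where
R_ij counts the nodes of predicted cluster C_i inside reference cluster
K_j:

    recall    = sum_j max_i R_ij / sum_ij R_ij      (cluster completeness)
    precision = sum_i max_j R_ij / sum_ij R_ij      (cluster purity)
    F         = 2 P R / (P + R)

The Jaccard index compares the two partitions at the node-pair level:
J = a11 / (a11 + a10 + a01), with a11 pairs co-clustered in both, a10
co-clustered only in the reference, a01 only in the prediction.

Nodes present in only one of the two partitions are excluded from all
metrics (their counts are logged and reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_io import ClusterAssignment

__all__ = [
    "ContingencyTable",
    "EvalReport",
    "contingency",
    "recall_precision_f",
    "jaccard_index",
    "evaluate",
    "binned_report",
    "SIZE_BINS",
]

logger = logging.getLogger(__name__)

#: Reference-cluster size classes used as a proxy for expression level.
SIZE_BINS: tuple[tuple[str, int, int], ...] = (
    ("<=5", 1, 5),
    ("5-10", 6, 10),
    ("10-50", 11, 50),
    (">=50", 51, np.iinfo(np.int64).max),
)


@dataclass
class ContingencyTable:
    """Cross-tabulation of a predicted vs a reference clustering.

    ``matrix[i, j]`` counts common nodes in predicted cluster i and
    reference cluster j; ``pred_only``/``ref_only`` are the node counts
    dropped from the comparison because they appear in one side only.
    """

    matrix: np.ndarray
    pred_clusters: list[frozenset[int]]
    ref_clusters: list[frozenset[int]]
    pred_only: int = 0
    ref_only: int = 0

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def K(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class EvalReport:
    """All accuracy metrics for one predicted/reference pair."""

    recall: float
    precision: float
    f_measure: float
    jaccard: float
    a11: int
    a00: int
    a10: int
    a01: int
    n_common: int
    n_pred_only: int
    n_ref_only: int

    def as_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "jaccard": self.jaccard,
            "a11": self.a11,
            "a00": self.a00,
            "a10": self.a10,
            "a01": self.a01,
            "n_common": self.n_common,
            "n_pred_only": self.n_pred_only,
            "n_ref_only": self.n_ref_only,
        }


def contingency(pred: ClusterAssignment, ref: ClusterAssignment) -> ContingencyTable:
    """Build the contingency table over nodes present in both partitions.

    Clusters follow canonical order (smallest member first); clusters
    left empty after restriction to the common support are dropped.
    """
    pred = pred.canonical()
    ref = ref.canonical()
    common = pred.support() & ref.support()
    pred_only = len(pred.support() - common)
    ref_only = len(ref.support() - common)
    if pred_only or ref_only:
        logger.warning(
            "dropping nodes outside the common support: %d prediction-only, "
            "%d reference-only", pred_only, ref_only)
    pred_clusters = [c & common for c in pred.clusters if c & common]
    ref_clusters = [c & common for c in ref.clusters if c & common]
    if not common:
        logger.warning("predicted and reference partitions share no nodes")
        return ContingencyTable(np.zeros((0, 0), dtype=np.int64), [], [],
                                pred_only, ref_only)
    ref_of: dict[int, int] = {}
    for j, kj in enumerate(ref_clusters):
        for node in kj:
            ref_of[node] = j
    matrix = np.zeros((len(pred_clusters), len(ref_clusters)), dtype=np.int64)
    for i, ci in enumerate(pred_clusters):
        for node in ci:
            matrix[i, ref_of[node]] += 1
    return ContingencyTable(matrix, pred_clusters, ref_clusters,
                            pred_only, ref_only)


def recall_precision_f(table: ContingencyTable) -> tuple[float, float, float]:
    """Recall, precision and their harmonic mean from a contingency table."""
    total = int(table.matrix.sum())
    if total == 0:
        raise ValueError("contingency table is empty; no common nodes")
    recall = float(table.matrix.max(axis=0).sum()) / total
    precision = float(table.matrix.max(axis=1).sum()) / total
    f = 0.0 if recall + precision == 0 else 2 * precision * recall / (precision + recall)
    return recall, precision, f


def _pair_count(sizes: np.ndarray) -> int:
    return int((sizes * (sizes - 1) // 2).sum())


def jaccard_index(pred: ClusterAssignment,
                  ref: ClusterAssignment) -> tuple[float, int, int, int, int]:
    """Pair-level Jaccard index and the four pair counts (a11, a00, a10, a01).

    Computed over the common support, which must contain at least two
    nodes.  When neither partition co-clusters any pair (both all
    singletons) the index is defined as 1.
    """
    table = contingency(pred, ref)
    n = int(table.matrix.sum())
    if n < 2:
        raise ValueError("need at least 2 common nodes for pair counting")
    a11 = _pair_count(table.matrix.reshape(-1))
    pred_pairs = _pair_count(table.matrix.sum(axis=1))
    ref_pairs = _pair_count(table.matrix.sum(axis=0))
    a01 = pred_pairs - a11
    a10 = ref_pairs - a11
    a00 = n * (n - 1) // 2 - a11 - a10 - a01
    denom = a11 + a10 + a01
    jac = 1.0 if denom == 0 else a11 / denom
    return jac, a11, a00, a10, a01


def evaluate(pred: ClusterAssignment, ref: ClusterAssignment) -> EvalReport:
    """Full evaluation of a predicted clustering against a reference."""
    table = contingency(pred, ref)
    recall, precision, f = recall_precision_f(table)
    jac, a11, a00, a10, a01 = jaccard_index(pred, ref)
    return EvalReport(recall=recall, precision=precision, f_measure=f,
                      jaccard=jac, a11=a11, a00=a00, a10=a10, a01=a01,
                      n_common=int(table.matrix.sum()),
                      n_pred_only=table.pred_only, n_ref_only=table.ref_only)


def binned_report(pred: ClusterAssignment, ref: ClusterAssignment) -> pd.DataFrame:
    """Mean per-cluster recall/precision by reference-cluster size bin.

    Reference-cluster size proxies gene expression.  Per reference
    cluster j, recall_j = max_i R_ij / |K_j|; per predicted cluster i,
    precision_i = max_j R_ij / |C_i|, attributed to the bin of its
    best-matching reference cluster.
    """
    table = contingency(pred, ref)
    if table.matrix.size == 0:
        raise ValueError("no common nodes to bin")
    ref_sizes = table.matrix.sum(axis=0)
    rec_per_ref = table.matrix.max(axis=0) / ref_sizes
    pred_sizes = table.matrix.sum(axis=1)
    prec_per_pred = table.matrix.max(axis=1) / pred_sizes
    best_ref = table.matrix.argmax(axis=1)
    rows = []
    for label, lo, hi in SIZE_BINS:
        in_bin_ref = (ref_sizes >= lo) & (ref_sizes <= hi)
        in_bin_pred = (ref_sizes[best_ref] >= lo) & (ref_sizes[best_ref] <= hi)
        rows.append({
            "bin": label,
            "n_ref_clusters": int(in_bin_ref.sum()),
            "mean_recall": float(rec_per_ref[in_bin_ref].mean()) if in_bin_ref.any() else np.nan,
            "mean_precision": float(prec_per_pred[in_bin_pred].mean()) if in_bin_pred.any() else np.nan,
        })
    return pd.DataFrame(rows)
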