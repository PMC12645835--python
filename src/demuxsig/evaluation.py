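"""Classification and clustering evaluation.

Classification quality is summarized by accuracy, per-class and macro
precision/recall/F1, the confusion matrix and per-class one-vs-rest
ROC AUC.  Clusterings are compared to ground-truth barcode labels via
homogeneity ``h = 1 - H(class|cluster)/H(class)`` and completeness
``c = 1 - H(cluster|class)/H(cluster)`` (entropies from empirical joint
counts; the base cancels in the ratios), plus a majority-vote protocol
that maps every cluster to its most frequent true label and scores
read-level accuracy under that mapping.

Conventions: zero-denominator precision/recall are reported as 0 and the
affected classes flagged; all tie-breaks (argmax, majority vote) resolve
to the lowest index.  Standard metrics are computed with scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    confusion_matrix,
    homogeneity_completeness_v_measure,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .signal_io import SignalSet

__all__ = [
    "EvalReport",
    "ClusteringReport",
    "classification_metrics",
    "roc_auc_ovr",
    "per_class_auc",
    "homogeneity_completeness",
    "majority_vote_map",
    "evaluate",
    "read_clusters_table",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class EvalReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    undefined_precision: list[int] = field(default_factory=list)
    undefined_recall: list[int] = field(default_factory=list)
    per_class_auc: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "accuracy": self.accuracy,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "undefined_precision": self.undefined_precision,
            "undefined_recall": self.undefined_recall,
        }
        if self.per_class_auc is not None:
            d["per_class_auc"] = self.per_class_auc.tolist()
        return d

    def summary(self) -> str:
        lines = [
            f"accuracy        {self.accuracy:.4f}",
            f"macro precision {self.macro_precision:.4f}",
            f"macro recall    {self.macro_recall:.4f}",
            f"macro F1        {self.macro_f1:.4f}",
        ]
        for c in range(self.confusion.shape[0]):
            row = (f"class {c}: P={self.precision[c]:.4f} "
                   f"R={self.recall[c]:.4f} F1={self.f1[c]:.4f}")
            if self.per_class_auc is not None:
                row += f" AUC={self.per_class_auc[c]:.4f}"
            lines.append(row)
        return "\n".join(lines)


@dataclass
class ClusteringReport:
    homogeneity: float
    completeness: float
    mapped_accuracy: float
    cluster_to_label: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
            "mapped_accuracy": self.mapped_accuracy,
            "cluster_to_label": {str(k): int(v) for k, v in self.cluster_to_label.items()},
        }


def _check_pair(y_true, y_other) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_other = np.asarray(y_other, dtype=np.int64)
    if y_true.shape != y_other.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError("inputs must be equal-length non-empty 1-D vectors")
    return y_true, y_other


def classification_metrics(y_true, y_pred, C: int) -> EvalReport:
    """Accuracy, per-class and macro precision/recall/F1, confusion matrix.

    Rows of the confusion matrix are true classes, columns predictions.
    A class never predicted has precision 0 (flagged in
    ``undefined_precision``); a class absent from the truth has recall 0
    (flagged in ``undefined_recall``); macro scores are plain unweighted
    means, so they are always defined.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.min() < 0 or max(y_true.max(), y_pred.max()) >= C:
        raise ValueError(f"labels must lie in [0, {C})")
    labels = np.arange(C)
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    return EvalReport(
        accuracy=float(np.trace(conf) / conf.sum()),
        precision=prec, recall=rec, f1=f1,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        confusion=conf,
        undefined_precision=[int(c) for c in labels if conf[:, c].sum() == 0],
        undefined_recall=[int(c) for c in labels if conf[c, :].sum() == 0],
    )


def roc_auc_ovr(y_true, scores, c: int) -> float:
    """One-vs-rest AUC for class ``c`` from a (n, C) score matrix.

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over all
    positive/negative pairs (trapezoidal ROC integration).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != y_true.size:
        raise ValueError("scores must be an (n, C) matrix aligned with y_true")
    pos = y_true == c
    if pos.all() or not pos.any():
        raise ValueError(
            f"AUC undefined for class {c}: need at least one positive and one negative"
        )
    return float(roc_auc_score(pos.astype(int), scores[:, c]))


def per_class_auc(y_true, scores) -> np.ndarray:
    """One-vs-rest AUC for every class; NaN where undefined."""
    scores = np.asarray(scores, dtype=float)
    out = np.full(scores.shape[1], np.nan)
    for c in range(scores.shape[1]):
        try:
            out[c] = roc_auc_ovr(y_true, scores, c)
        except ValueError:
            pass
    return out


def homogeneity_completeness(y_true, clusters) -> tuple[float, float]:
    """Entropy-based cluster purity (h) and class concentration (c).

    ``h = 1 - H(class|cluster)/H(class)`` (1 when the class labeling has
    zero entropy) and ``c = 1 - H(cluster|class)/H(cluster)`` (1 when the
    clustering has zero entropy).
    """
    y_true, clusters = _check_pair(y_true, clusters)
    h, c, _ = homogeneity_completeness_v_measure(y_true, clusters)
    return float(h), float(c)


def majority_vote_map(y_true, clusters) -> ClusteringReport:
    """Map every cluster to its most frequent true label and score reads.

    Ties go to the lowest label index.  ``mapped_accuracy`` is the fraction
    of reads whose cluster's assigned label matches their true label.
    """
    y_true, clusters = _check_pair(y_true, clusters)
    mapping: dict[int, int] = {}
    for cl in np.unique(clusters):
        members = y_true[clusters == cl]
        counts = np.bincount(members)
        mapping[int(cl)] = int(np.argmax(counts))   # argmax ties -> lowest index
    mapped = np.array([mapping[int(cl)] for cl in clusters])
    h, c = homogeneity_completeness(y_true, clusters)
    return ClusteringReport(
        homogeneity=h,
        completeness=c,
        mapped_accuracy=float(np.mean(mapped == y_true)),
        cluster_to_label=mapping,
    )


def read_clusters_table(path) -> dict[str, int]:
    """Read a two-column ``read_id<TAB>cluster_id`` table (no header)."""
    out: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if parts[0] in out:
                raise ValueError(f"{path}:{lineno}: duplicate read_id {parts[0]!r}")
            out[parts[0]] = int(parts[1])
    return out


def evaluate(
    pred_ids: list[str],
    y_pred: np.ndarray,
    probs: np.ndarray | None,
    truth: SignalSet,
    clusters: dict[str, int] | None = None,
) -> tuple[EvalReport, ClusteringReport | None]:
    """Join predictions to a labeled dataset on read_id and score them.

    Row order of the prediction file is irrelevant; any read present in
    only one of the two inputs is an error naming the offenders.
    """
    truth_labels = {s.read_id: s.label for s in truth.signals}
    if any(lab is None for lab in truth_labels.values()):
        raise ValueError("truth dataset contains unlabeled reads")
    missing = sorted(set(truth_labels) - set(pred_ids))
    extra = sorted(set(pred_ids) - set(truth_labels))
    if missing or extra:
        raise ValueError(
            f"read_id mismatch between predictions and truth: "
            f"missing from predictions {missing[:5]}, unknown {extra[:5]}"
        )
    y_true = np.array([truth_labels[rid] for rid in pred_ids], dtype=np.int64)
    report = classification_metrics(y_true, np.asarray(y_pred), truth.n_classes)
    if probs is not None:
        report.per_class_auc = per_class_auc(y_true, probs)

    clus_report = None
    if clusters is not None:
        missing_c = sorted(set(pred_ids) - set(clusters))
        if missing_c:
            raise ValueError(f"reads missing from cluster table: {missing_c[:5]}")
        cl = np.array([clusters[rid] for rid in pred_ids], dtype=np.int64)
        clus_report = majority_vote_map(y_true, cl)
    return report, clus_report


def write_report_json(path, report: EvalReport, clustering: ClusteringReport | None = None):
    doc = {"classification": report.to_dict()}
    if clustering is not None:
        doc["clustering"] = clustering.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
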