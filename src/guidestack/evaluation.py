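"""Metrics and validation schemes for off-target classifiers.

Implements ROC-AUC and PR-AUC (average precision) with explicit
undefined-metric errors, stratified single-split and k-fold
cross-validation, and leave-one-sgRNA-out (LOSO) validation in which
guides with few positives are merged — ascending by positive count —
until every held-out group carries at least ``min_pos`` (default 30)
positive pairs.  LOSO reports both the pooled "global" metrics over all
held-out predictions and the per-group averages; under heavy imbalance
the two can differ substantially because small groups contribute equally
to the average but little to the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoding import GuideTargetPair, tokenize_pairs
from .model import ModelConfig, build_model


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (single-class input)."""


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties counted 1/2 (the rank / Mann-Whitney formulation).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if np.unique(labels).size < 2:
        raise UndefinedMetricError("ROC-AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def pr_auc(labels, scores) -> float:
    """Area under the precision-recall curve as average precision:
    sum over score-descending threshold steps of (delta recall x precision),
    with tied scores processed as one threshold block."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.sum() == 0:
        raise UndefinedMetricError("PR-AUC undefined: no positive examples")
    return float(average_precision_score(labels, scores))


@dataclass
class EvalReport:
    """ROC/PR curves and areas for one scored set."""

    roc_auc: float
    pr_auc: float
    roc_points: np.ndarray  # columns: fpr, tpr
    pr_points: np.ndarray  # columns: recall, precision
    n_pos: int
    n_neg: int

    @classmethod
    def from_scores(cls, labels, scores) -> "EvalReport":
        labels = np.asarray(labels)
        scores = np.asarray(scores)
        auc = roc_auc(labels, scores)
        ap = pr_auc(labels, scores)
        fpr, tpr, _ = roc_curve(labels, scores)
        prec, rec, _ = precision_recall_curve(labels, scores)
        return cls(
            roc_auc=auc,
            pr_auc=ap,
            roc_points=np.column_stack([fpr, tpr]),
            pr_points=np.column_stack([rec[::-1], prec[::-1]]),
            n_pos=int(labels.sum()),
            n_neg=int((labels == 0).sum()),
        )

    def write(self, path_prefix) -> None:
        """Write a key:value summary plus curve tables next to it."""
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        lines = [
            f"roc_auc: {self.roc_auc:.6f}",
            f"pr_auc: {self.pr_auc:.6f}",
            f"n_pos: {self.n_pos}",
            f"n_neg: {self.n_neg}",
        ]
        Path(f"{prefix}.txt").write_text("\n".join(lines) + "\n")
        np.savetxt(
            f"{prefix}_roc.csv", self.roc_points, delimiter=",",
            header="fpr,tpr", comments="",
        )
        np.savetxt(
            f"{prefix}_pr.csv", self.pr_points, delimiter=",",
            header="recall,precision", comments="",
        )


def single_split(
    pairs: list[GuideTargetPair], val_fraction: float = 0.1, seed: int = 0
) -> tuple[list[GuideTargetPair], list[GuideTargetPair]]:
    """Stratified train/validation split leaving ``val_fraction`` out."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must be in (0,1), got {val_fraction}")
    labels = [p.label for p in pairs]
    train, val = train_test_split(
        pairs, test_size=val_fraction, stratify=labels, random_state=seed
    )
    return train, val


def kfold_split(
    pairs: list[GuideTargetPair], k_folds: int = 5, seed: int = 0
) -> list[tuple[list[GuideTargetPair], list[GuideTargetPair]]]:
    """Stratified k-fold partition; every pair validated exactly once."""
    if k_folds < 2:
        raise ValueError(f"k_folds must be >= 2, got {k_folds}")
    if k_folds > len(pairs):
        raise ValueError(f"k_folds={k_folds} exceeds n={len(pairs)}")
    labels = np.array([p.label for p in pairs])
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    out = []
    for train_idx, val_idx in skf.split(np.zeros(len(pairs)), labels):
        out.append(([pairs[i] for i in train_idx], [pairs[i] for i in val_idx]))
    return out


@dataclass
class GroupAssignment:
    """Ordered partition of guide ids into LOSO evaluation groups."""

    groups: list[list[str]]
    positive_counts: list[int]
    degenerate: bool = False  # whole dataset has fewer positives than min_pos

    def group_of(self) -> dict[str, int]:
        return {g: i for i, grp in enumerate(self.groups) for g in grp}


def group_guides_for_loso(
    pairs: list[GuideTargetPair], min_pos: int = 30
) -> GroupAssignment:
    """Merge guides, ascending by positive-pair count, until each group
    holds at least ``min_pos`` positives.

    Guides are sorted by positive count (ties broken by guide id) and
    accumulated greedily into the current group, which closes as soon as
    its positive total reaches ``min_pos``.  A trailing group below the
    threshold merges into the previous group; a dataset whose total is
    below the threshold yields a single group flagged degenerate.
    """
    if min_pos < 1:
        raise ValueError(f"min_pos must be >= 1, got {min_pos}")
    pos_counts: dict[str, int] = {}
    for p in pairs:
        pos_counts.setdefault(p.guide_id, 0)
        if p.label == 1:
            pos_counts[p.guide_id] += 1
    if sum(pos_counts.values()) == 0:
        raise ValueError("dataset has no positive pairs; LOSO grouping undefined")

    ordered = sorted(pos_counts, key=lambda g: (pos_counts[g], g))
    groups: list[list[str]] = []
    counts: list[int] = []
    current: list[str] = []
    current_pos = 0
    for g in ordered:
        current.append(g)
        current_pos += pos_counts[g]
        if current_pos >= min_pos:
            groups.append(current)
            counts.append(current_pos)
            current, current_pos = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
            counts[-1] += current_pos
        else:
            groups.append(current)
            counts.append(current_pos)
    degenerate = len(groups) == 1 and counts[0] < min_pos
    return GroupAssignment(groups=groups, positive_counts=counts, degenerate=degenerate)


@dataclass
class LosoResult:
    """Per-group and pooled outcomes of leave-one-sgRNA-out validation."""

    assignment: GroupAssignment
    per_group: list[EvalReport | None]  # None where the held-out group is single-class
    global_report: EvalReport
    mean_roc_auc: float
    mean_pr_auc: float
    skipped_groups: list[int] = field(default_factory=list)


def run_loso(
    pairs: list[GuideTargetPair],
    cfg: ModelConfig,
    min_pos: int = 30,
    seed: int | None = None,
) -> LosoResult:
    """Train once per group on all other groups and score the held-out one.

    Every pair is scored exactly once; the pooled predictions form the
    global report while per-group AUCs (where defined) are averaged.
    Groups whose held-out pairs are single-class have no per-group report
    but still enter the global pool.
    """
    assignment = group_guides_for_loso(pairs, min_pos=min_pos)
    if len(assignment.groups) < 2:
        raise ValueError("LOSO requires at least two guide groups after merging")
    if seed is not None:
        cfg = ModelConfig.from_dict({**cfg.to_dict(), "seed": seed})
    group_of = assignment.group_of()

    all_labels: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    per_group: list[EvalReport | None] = []
    skipped: list[int] = []

    for gi in range(len(assignment.groups)):
        held = [p for p in pairs if group_of[p.guide_id] == gi]
        rest = [p for p in pairs if group_of[p.guide_id] != gi]
        X_tr, y_tr, _ = tokenize_pairs(rest, None)
        X_te, y_te, _ = tokenize_pairs(held, None)
        model = build_model(cfg)
        model.fit(X_tr, y_tr)
        scores = model.predict_proba(X_te)[:, 1]
        all_labels.append(y_te)
        all_scores.append(scores)
        try:
            per_group.append(EvalReport.from_scores(y_te, scores))
        except UndefinedMetricError:
            per_group.append(None)
            skipped.append(gi)

    labels = np.concatenate(all_labels)
    scores = np.concatenate(all_scores)
    global_report = EvalReport.from_scores(labels, scores)
    defined = [r for r in per_group if r is not None]
    return LosoResult(
        assignment=assignment,
        per_group=per_group,
        global_report=global_report,
        mean_roc_auc=float(np.mean([r.roc_auc for r in defined])),
        mean_pr_auc=float(np.mean([r.pr_auc for r in defined])),
        skipped_groups=skipped,
    )
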