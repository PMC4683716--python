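"""Per-compound ranking metrics and the compound-wise cross-validation protocol.

Performance is summarized per compound: for each compound with at least one
known target in the candidate panel, the predicted scores over the panel
are compared with the 0/1 target labels via ROC AUC and the area under the
precision-recall curve, and the report averages these over evaluable
compounds.  Top-k ratios count the compounds with at least one known target
among their k highest-scoring proteins.

Cross-validation splits *compounds* into k folds; the protein panel is
common to training and test, simulating the practical task of predicting
targets for a new compound against a fixed panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from . import pkr as _pkr
from .benchmark import InteractionSet
from .direct import ScoreMatrix, direct_scores
from .io_formats import LabeledMatrix, SequenceSet
from .similarity import (
    CrossSimilarityMatrix,
    SimilarityMatrix,
    average_similarity,
    normalized_sequence_similarity,
    pearson_similarity,
    protein_expression_profiles,
    tanimoto_similarity,
)

__all__ = [
    "FoldSplit",
    "EvaluationReport",
    "rank_metrics",
    "topk_hit",
    "evaluate",
    "make_folds",
    "cross_validate",
    "APPROACHES",
]

logger = logging.getLogger(__name__)

APPROACHES = ("transcriptomic", "chemogenomic", "integrative", "direct-absolute")


@dataclass
class FoldSplit:
    """Assignment of each compound to one of k folds (1-based)."""

    k: int
    assignment: dict[str, int]
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignment.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignment.items() if f != fold)


@dataclass
class EvaluationReport:
    """Per-compound AUC/AUPR plus their means and Top-k hit ratios.

    ``fold_of`` records the test fold of each compound when the report
    comes from cross-validation (empty for single-pass evaluation).
    """

    per_compound: dict[str, tuple[float, float]]
    mean_auc: float
    mean_aupr: float
    top10_ratio: float
    top50_ratio: float
    n_evaluable_compounds: int
    fold_of: dict[str, int] = dataclass_field(default_factory=dict)

    def fold_summary(self) -> dict[int, tuple[float, float]]:
        """Mean (AUC, AUPR) of evaluable compounds per fold."""
        out: dict[int, tuple[float, float]] = {}
        for fold in sorted(set(self.fold_of.values())):
            vals = [self.per_compound[c] for c, f in self.fold_of.items()
                    if f == fold and c in self.per_compound]
            if vals:
                arr = np.array(vals)
                out[fold] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
        return out

    def summary(self) -> dict[str, float]:
        return {
            "mean_auc": self.mean_auc,
            "mean_aupr": self.mean_aupr,
            "top10_ratio": self.top10_ratio,
            "top50_ratio": self.top50_ratio,
            "n_evaluable_compounds": self.n_evaluable_compounds,
        }


def rank_metrics(scores: np.ndarray, labels: np.ndarray) -> Optional[tuple[float, float]]:
    """(AUC, AUPR) of a score vector against 0/1 labels.

    AUC is the probability that a random positive outranks a random
    negative, ties counting one half (the midrank formula, identical to
    trapezoidal ROC area).  AUPR is the area under the precision-recall
    step curve with thresholds at distinct score values.  Returns ``None``
    (not evaluable) when labels are all positive or all negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores, method="average")
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = pos[order]
    tp = np.cumsum(l_sorted)
    n_seen = np.arange(1, len(labels) + 1)
    # group by distinct score: take the last index of each tie block
    last = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.append(last, len(s_sorted) - 1)
    recall = tp[idx] / n_pos
    precision = tp[idx] / n_seen[idx]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    aupr = float(np.sum((recall - prev_recall) * precision))
    return float(auc), aupr


def topk_hit(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int,
    ids: Optional[Sequence[str]] = None,
) -> bool:
    """True iff any positive lies among the k highest scores.

    Score ties are broken by ascending entity ID (index order when no IDs
    are given) before cutting at k, so the outcome is deterministic.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not (labels == 1).any():
        raise ValueError("topk_hit requires at least one positive label")
    if ids is None:
        order = np.lexsort((np.arange(len(scores)), -scores))
    else:
        order = np.lexsort((np.asarray(ids, dtype=object), -scores))
    top = order[:k]
    return bool((labels[top] == 1).any())


def evaluate(scores: ScoreMatrix, gold: InteractionSet) -> EvaluationReport:
    """Per-compound metrics of a score matrix against the gold standard.

    The candidate panel is the score matrix's protein list; compounds with
    no known target in the panel (or with every panel protein a target) are
    excluded from all averages and ratios.
    """
    panel = scores.protein_ids
    per_compound: dict[str, tuple[float, float]] = {}
    hits10 = hits50 = 0
    for i, comp in enumerate(scores.compound_ids):
        if comp not in set(gold.compounds):
            continue
        targets = gold.targets_of(comp)
        labels = np.array([1 if p in targets else 0 for p in panel])
        metrics = rank_metrics(scores.scores[i], labels)
        if metrics is None:
            continue
        per_compound[comp] = metrics
        if topk_hit(scores.scores[i], labels, 10, ids=panel):
            hits10 += 1
        if topk_hit(scores.scores[i], labels, 50, ids=panel):
            hits50 += 1
    n = len(per_compound)
    if n == 0:
        raise ValueError("no evaluable compound (none has both a positive and a negative in the panel)")
    aucs = np.array([m[0] for m in per_compound.values()])
    auprs = np.array([m[1] for m in per_compound.values()])
    return EvaluationReport(
        per_compound=per_compound,
        mean_auc=float(aucs.mean()),
        mean_aupr=float(auprs.mean()),
        top10_ratio=hits10 / n,
        top50_ratio=hits50 / n,
        n_evaluable_compounds=n,
    )


def make_folds(compound_ids: Sequence[str], k: int, seed: int) -> FoldSplit:
    """Random partition of compounds into k folds of near-equal size."""
    ids = sorted(compound_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of compounds ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {ids[j]: (i % k) + 1 for i, j in enumerate(perm)}
    return FoldSplit(k=k, assignment=assignment, seed=seed)


def _compound_kernel(
    approach: str,
    expression: Optional[LabeledMatrix],
    descriptors: Optional[LabeledMatrix],
    compounds: Sequence[str],
    use_absolute_expression: bool,
) -> SimilarityMatrix:
    def expr_kernel() -> SimilarityMatrix:
        if expression is None:
            raise ValueError(f"approach {approach!r} requires an expression matrix")
        sub = expression.take_rows(list(compounds))
        vals = np.abs(sub.values) if use_absolute_expression else sub.values
        return pearson_similarity(LabeledMatrix(sub.row_ids, sub.col_ids, vals))

    def chem_kernel() -> SimilarityMatrix:
        if descriptors is None:
            raise ValueError(f"approach {approach!r} requires a descriptor table")
        return tanimoto_similarity(descriptors.take_rows(list(compounds)))

    if approach == "transcriptomic":
        return expr_kernel()
    if approach == "chemogenomic":
        return chem_kernel()
    return average_similarity(expr_kernel(), chem_kernel())


def _protein_kernel(
    approach: str,
    expression: Optional[LabeledMatrix],
    sequences: Optional[SequenceSet],
    protein_gene_map: Optional[Mapping[str, str]],
    panel: Sequence[str],
    use_absolute_expression: bool,
) -> SimilarityMatrix:
    def expr_kernel() -> SimilarityMatrix:
        if expression is None or protein_gene_map is None:
            raise ValueError(f"approach {approach!r} requires expression and a protein-gene map")
        profiles = protein_expression_profiles(expression, dict(protein_gene_map))
        missing = set(panel) - set(profiles.row_ids)
        if missing:
            raise ValueError(f"panel proteins without expression profiles: {sorted(missing)[:5]}")
        sub = profiles.take_rows(list(panel))
        vals = np.abs(sub.values) if use_absolute_expression else sub.values
        return pearson_similarity(LabeledMatrix(sub.row_ids, sub.col_ids, vals))

    def seq_kernel() -> SimilarityMatrix:
        if sequences is None:
            raise ValueError(f"approach {approach!r} requires protein sequences")
        missing = set(panel) - set(sequences.ids)
        if missing:
            raise ValueError(f"panel proteins without sequences: {sorted(missing)[:5]}")
        return normalized_sequence_similarity(sequences.subset(list(panel)))

    if approach == "transcriptomic":
        return expr_kernel()
    if approach == "chemogenomic":
        return seq_kernel()
    return average_similarity(expr_kernel(), seq_kernel())


def cross_validate(
    gold: InteractionSet,
    approach: str,
    expression: Optional[LabeledMatrix] = None,
    descriptors: Optional[LabeledMatrix] = None,
    sequences: Optional[SequenceSet] = None,
    protein_gene_map: Optional[Mapping[str, str]] = None,
    k: int = 5,
    seed: int = 0,
    lam: float = 1.0,
    use_absolute_expression: bool = True,
) -> EvaluationReport:
    """Compound-wise k-fold cross-validation of one prediction approach.

    For each fold, a PKR model is trained on the remaining compounds' full
    0/1 label matrix over the common protein panel and applied to the held
    out compounds; per-compound metrics are pooled across folds into one
    report.  The ``direct-absolute`` approach needs no training and is
    evaluated on all compounds at once.

    ``use_absolute_expression`` computes expression kernels from |X|, the
    scoring scheme retained after comparing X, -X and |X| with the direct
    method: fold-change magnitude, not direction, carries the target signal.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")

    if approach == "direct-absolute":
        if expression is None or protein_gene_map is None:
            raise ValueError("approach 'direct-absolute' requires expression and a protein-gene map")
        panel_map = {p: g for p, g in protein_gene_map.items() if p in set(gold.proteins)}
        scores = direct_scores(
            expression.take_rows(list(gold.compounds)), panel_map, mode="absolute"
        )
        return evaluate(scores, gold)

    compounds = sorted(gold.compounds)
    panel = sorted(gold.proteins)
    missing_feat = _missing_compounds(approach, expression, descriptors, compounds)
    if missing_feat:
        raise ValueError(f"compounds absent from the feature inputs: {missing_feat[:5]}")

    k_comp_full = _compound_kernel(approach, expression, descriptors, compounds, use_absolute_expression)
    k_prot = _pkr.make_psd(
        _protein_kernel(approach, expression, sequences, protein_gene_map, panel, use_absolute_expression)
    )
    folds = make_folds(compounds, k, seed)
    labels_full = _pkr.label_matrix(gold.positives, compounds, panel)
    cpos = {c: i for i, c in enumerate(compounds)}

    all_scores = np.zeros((len(compounds), len(panel)))
    for fold in range(1, k + 1):
        train_ids = folds.train_ids(fold)
        test_ids = folds.test_ids(fold)
        k_train = _pkr.make_psd(k_comp_full.take(train_ids))
        y = labels_full[[cpos[c] for c in train_ids], :]
        model = _pkr.train(k_train, k_prot, y, lam=lam, kernel_kind=approach)
        k_cross = k_comp_full.cross(test_ids, train_ids)
        fold_scores = _pkr.predict(model, k_cross, k_prot)
        for r, c in enumerate(test_ids):
            all_scores[cpos[c], :] = fold_scores.scores[r, :]
    report = evaluate(ScoreMatrix(compounds, panel, all_scores), gold)
    report.fold_of = dict(folds.assignment)
    return report


def _missing_compounds(
    approach: str,
    expression: Optional[LabeledMatrix],
    descriptors: Optional[LabeledMatrix],
    compounds: Sequence[str],
) -> list[str]:
    missing: list[str] = []
    if approach in ("transcriptomic", "integrative") and expression is not None:
        missing += [c for c in compounds if c not in set(expression.row_ids)]
    if approach in ("chemogenomic", "integrative") and descriptors is not None:
        missing += [c for c in compounds if c not in set(descriptors.row_ids)]
    return sorted(set(missing))
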