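"""Similarity kernels over compounds and proteins.

Four kernels feed the pairwise classifier:

* compound expression similarity — Pearson correlation of expression rows;
* protein expression similarity — Pearson correlation of expression columns
  for the genes encoding the proteins;
* chemical structure similarity — generalized Jaccard (real-valued
  Tanimoto) over nonnegative descriptor counts;
* protein sequence similarity — Smith-Waterman local alignment scores under
  BLOSUM62 with affine gaps, cosine-normalized by self-alignment so the
  diagonal is 1.

Each kernel comes in a square (all-vs-all) and a rectangular (query-vs-
reference) form; the rectangular form scores held-out compounds against
training compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import LabeledMatrix, SequenceSet

__all__ = [
    "SimilarityMatrix",
    "CrossSimilarityMatrix",
    "pearson_similarity",
    "tanimoto_similarity",
    "smith_waterman_score",
    "normalized_sequence_similarity",
    "average_similarity",
    "protein_expression_profiles",
]

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one set of entities."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-8, rtol=0):
            raise ValueError("similarity matrix is not symmetric")
        # enforce exact symmetry for downstream eigendecompositions
        self.values = (self.values + self.values.T) / 2.0

    def take(self, ids: Sequence[str]) -> "SimilarityMatrix":
        pos = {e: i for i, e in enumerate(self.ids)}
        idx = [pos[e] for e in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def cross(self, query_ids: Sequence[str], reference_ids: Sequence[str]) -> "CrossSimilarityMatrix":
        pos = {e: i for i, e in enumerate(self.ids)}
        qi = [pos[e] for e in query_ids]
        ri = [pos[e] for e in reference_ids]
        return CrossSimilarityMatrix(list(query_ids), list(reference_ids), self.values[np.ix_(qi, ri)])


@dataclass
class CrossSimilarityMatrix:
    """Rectangular similarity of query entities against reference entities."""

    query_ids: list[str]
    reference_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_ids), len(self.reference_ids)):
            raise ValueError("cross-similarity shape does not match ID lists")


def _check_same_features(profiles: LabeledMatrix, reference: LabeledMatrix) -> None:
    if profiles.col_ids != reference.col_ids:
        raise ValueError("query and reference feature IDs differ (order-sensitive)")


def pearson_similarity(
    profiles: LabeledMatrix, reference: Optional[LabeledMatrix] = None
) -> SimilarityMatrix | CrossSimilarityMatrix:
    """Pearson correlation between row profiles.

    Rows with zero variance correlate 0 with everything (a warning is
    logged), except that the diagonal of the square form is forced to 1.
    """
    if len(profiles.col_ids) < 2:
        raise ValueError("Pearson similarity requires at least 2 features")

    def _standardize(m: LabeledMatrix) -> tuple[np.ndarray, np.ndarray]:
        x = m.values - m.values.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(x, axis=1)
        flat = norms == 0
        if flat.any():
            logger.warning(
                "%d zero-variance profile(s); similarity set to 0: %s",
                flat.sum(),
                [m.row_ids[i] for i in np.flatnonzero(flat)[:5]],
            )
        safe = np.where(flat, 1.0, norms)
        return x / safe[:, None], flat

    xq, flat_q = _standardize(profiles)
    if reference is None:
        sim = xq @ xq.T
        sim[flat_q, :] = 0.0
        sim[:, flat_q] = 0.0
        np.clip(sim, -1.0, 1.0, out=sim)
        np.fill_diagonal(sim, 1.0)
        return SimilarityMatrix(list(profiles.row_ids), sim)
    _check_same_features(profiles, reference)
    xr, flat_r = _standardize(reference)
    sim = xq @ xr.T
    sim[flat_q, :] = 0.0
    sim[:, flat_r] = 0.0
    np.clip(sim, -1.0, 1.0, out=sim)
    return CrossSimilarityMatrix(list(profiles.row_ids), list(reference.row_ids), sim)


def _tanimoto_checks(m: LabeledMatrix) -> None:
    if np.any(m.values < 0):
        i, j = np.argwhere(m.values < 0)[0]
        raise ValueError(
            f"negative descriptor value for compound {m.row_ids[i]!r}, "
            f"descriptor {m.col_ids[j]!r}"
        )
    zero = ~m.values.any(axis=1)
    if zero.any():
        raise ValueError(
            f"all-zero descriptor vector for compound {m.row_ids[int(np.flatnonzero(zero)[0])]!r}"
        )


def tanimoto_similarity(
    descriptors: LabeledMatrix,
    reference: Optional[LabeledMatrix] = None,
    variant: str = "dot",
) -> SimilarityMatrix | CrossSimilarityMatrix:
    """Generalized Jaccard (Tanimoto for real-valued vectors).

    The default ``dot`` variant is x.y / (|x|^2 + |y|^2 - x.y); the
    ``minmax`` variant sum(min)/sum(max) is available but not the default.
    Descriptor values must be nonnegative and no row may be all zero.
    """
    if variant not in ("dot", "minmax"):
        raise ValueError(f"unknown Tanimoto variant: {variant!r}")
    _tanimoto_checks(descriptors)
    ref = descriptors if reference is None else reference
    if reference is not None:
        _check_same_features(descriptors, reference)
        _tanimoto_checks(reference)
    x, y = descriptors.values, ref.values
    if variant == "dot":
        dots = x @ y.T
        nx = np.einsum("ij,ij->i", x, x)
        ny = np.einsum("ij,ij->i", y, y)
        sim = dots / (nx[:, None] + ny[None, :] - dots)
    else:
        sim = np.empty((x.shape[0], y.shape[0]))
        for i in range(x.shape[0]):
            mins = np.minimum(x[i], y).sum(axis=1)
            maxs = np.maximum(x[i], y).sum(axis=1)
            sim[i] = mins / maxs
    if reference is None:
        np.fill_diagonal(sim, 1.0)
        return SimilarityMatrix(list(descriptors.row_ids), sim)
    return CrossSimilarityMatrix(list(descriptors.row_ids), list(ref.row_ids), sim)


def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def smith_waterman_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal local alignment score under BLOSUM62 with affine gaps.

    A gap of length L costs gap_open + (L - 1) * gap_extend.  Returns 0
    when no positive-scoring local alignment exists (the empty alignment).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    score = float(_aligner(gap_open, gap_extend).score(a, b))
    return max(score, 0.0)


def normalized_sequence_similarity(
    seqs: SequenceSet,
    reference: Optional[SequenceSet] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> SimilarityMatrix | CrossSimilarityMatrix:
    """Smith-Waterman scores cosine-normalized by self-alignment.

    Entry (i, j) = SW(i, j) / sqrt(SW(i, i) * SW(j, j)), so identical
    sequences score exactly 1 and unrelated ones approach 0.
    """
    aligner = _aligner(gap_open, gap_extend)

    def _self_scores(s: SequenceSet) -> np.ndarray:
        scores = np.array([aligner.score(seq, seq) for seq in s.entries.values()])
        if np.any(scores <= 0):
            bad = s.ids[int(np.flatnonzero(scores <= 0)[0])]
            raise ValueError(f"zero self-alignment score for sequence {bad!r}")
        return scores

    ids_q = seqs.ids
    self_q = _self_scores(seqs)
    if reference is None:
        n = len(ids_q)
        raw = np.zeros((n, n))
        sl = list(seqs.entries.values())
        for i in range(n):
            raw[i, i] = self_q[i]
            for j in range(i + 1, n):
                raw[i, j] = raw[j, i] = max(float(aligner.score(sl[i], sl[j])), 0.0)
        sim = raw / np.sqrt(np.outer(self_q, self_q))
        np.fill_diagonal(sim, 1.0)
        return SimilarityMatrix(ids_q, sim)
    self_r = _self_scores(reference)
    raw = np.zeros((len(ids_q), len(reference.ids)))
    for i, sq in enumerate(seqs.entries.values()):
        for j, sr in enumerate(reference.entries.values()):
            raw[i, j] = max(float(aligner.score(sq, sr)), 0.0)
    sim = raw / np.sqrt(np.outer(self_q, self_r))
    return CrossSimilarityMatrix(ids_q, reference.ids, sim)


def average_similarity(
    s1: SimilarityMatrix | CrossSimilarityMatrix,
    s2: SimilarityMatrix | CrossSimilarityMatrix,
) -> SimilarityMatrix | CrossSimilarityMatrix:
    """Element-wise average of two kernels over identical ID sets."""
    if isinstance(s1, SimilarityMatrix) != isinstance(s2, SimilarityMatrix):
        raise ValueError("cannot average a square kernel with a cross kernel")
    if isinstance(s1, SimilarityMatrix):
        if s1.ids != s2.ids:
            diff = sorted(set(s1.ids) ^ set(s2.ids))
            raise ValueError(f"kernel ID mismatch; symmetric difference: {diff}")
        return SimilarityMatrix(list(s1.ids), (s1.values + s2.values) / 2.0)
    if s1.query_ids != s2.query_ids or s1.reference_ids != s2.reference_ids:
        diff = sorted(
            (set(s1.query_ids) ^ set(s2.query_ids))
            | (set(s1.reference_ids) ^ set(s2.reference_ids))
        )
        raise ValueError(f"kernel ID mismatch; symmetric difference: {diff}")
    return CrossSimilarityMatrix(
        list(s1.query_ids), list(s1.reference_ids), (s1.values + s2.values) / 2.0
    )


def protein_expression_profiles(
    expression: LabeledMatrix, protein_gene_map: Mapping[str, str]
) -> LabeledMatrix:
    """Protein profiles = columns of the expression matrix for each protein's gene.

    Proteins whose gene is absent from the matrix are dropped with a
    warning; the result is a proteins x compounds matrix ready for
    ``pearson_similarity``.
    """
    col_pos = {c: j for j, c in enumerate(expression.col_ids)}
    kept = [p for p in protein_gene_map if protein_gene_map[p] in col_pos]
    dropped = [p for p in protein_gene_map if protein_gene_map[p] not in col_pos]
    if dropped:
        logger.warning("dropping %d protein(s) with no matching gene column: %s",
                       len(dropped), dropped[:5])
    # proteins may share a gene column, so index directly
    idx = [col_pos[protein_gene_map[p]] for p in kept]
    return LabeledMatrix(kept, list(expression.row_ids), expression.values[:, idx].T)
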