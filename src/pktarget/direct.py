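"""Direct fold-change scoring of compound-protein pairs.

The simplest target-prediction baseline: score a pair by the compound's
fold change at the gene encoding the protein.  Three scoring schemes are
supported — the raw value (high score = up-regulated gene), its negation
(high score = down-regulated gene), and the absolute value (high score =
strongly regulated in either direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import LabeledMatrix

__all__ = ["ScoreMatrix", "direct_scores", "MODES"]

MODES = ("raw", "negated", "absolute")


@dataclass
class ScoreMatrix:
    """Prediction scores for every (compound, protein) pair."""

    compound_ids: list[str]
    protein_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValueError("score matrix shape does not match ID lists")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite prediction score")


def direct_scores(
    x: LabeledMatrix, protein_gene_map: Mapping[str, str], mode: str = "absolute"
) -> ScoreMatrix:
    """Score proteins for each compound from its fold-change row.

    Proteins are ordered by ascending ID; proteins sharing a gene column
    receive identical scores (downstream ranking breaks ties by ID).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    col_pos = {c: j for j, c in enumerate(x.col_ids)}
    proteins = sorted(protein_gene_map)
    missing = [p for p in proteins if protein_gene_map[p] not in col_pos]
    if missing:
        raise KeyError(
            f"gene {protein_gene_map[missing[0]]!r} (protein {missing[0]!r}) "
            "not present in the expression matrix"
        )
    cols = [col_pos[protein_gene_map[p]] for p in proteins]
    scores = x.values[:, cols]
    if mode == "negated":
        scores = -scores
    elif mode == "absolute":
        scores = np.abs(scores)
    return ScoreMatrix(list(x.row_ids), proteins, scores.copy())
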