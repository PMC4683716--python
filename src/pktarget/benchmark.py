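"""Gold-standard pair universe and chemical-diversity benchmark series.

Interaction databases contain many near-identical derivatives of the same
lead compound; when such derivatives are split between training and test
folds, cross-validation overestimates accuracy.  The benchmark series
probes this by clustering compounds on chemical similarity (complete
linkage on distance 1 - Tanimoto), cutting the dendrogram at a sequence of
similarity thresholds, and keeping one representative per cluster.  Lower
thresholds give chemically more diverse benchmark subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import PairList
from .similarity import SimilarityMatrix

__all__ = [
    "InteractionSet",
    "BenchmarkSeries",
    "pair_counts",
    "cluster_representatives",
    "build_benchmark_series",
]


@dataclass
class InteractionSet:
    """Gold-standard positives plus the implied all-pairs universe.

    Every compound-protein pair not listed as a positive is, by definition,
    a negative example.
    """

    compounds: list[str]
    proteins: list[str]
    positives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        cset, pset = set(self.compounds), set(self.proteins)
        if len(cset) != len(self.compounds):
            raise ValueError("duplicate compound identifiers")
        if len(pset) != len(self.proteins):
            raise ValueError("duplicate protein identifiers")
        for c, p in self.positives:
            if c not in cset or p not in pset:
                raise ValueError(f"positive pair ({c!r}, {p!r}) references an unlisted entity")

    @classmethod
    def from_pairs(cls, pairs: PairList | Iterable[tuple[str, str]]) -> "InteractionSet":
        """Build the universe from a pair list: entities = those involved in positives."""
        raw = pairs.interactions() if isinstance(pairs, PairList) else list(pairs)
        compounds = sorted({c for c, _ in raw})
        proteins = sorted({p for _, p in raw})
        return cls(compounds, proteins, set(raw))

    def targets_of(self, compound: str) -> set[str]:
        return {p for c, p in self.positives if c == compound}

    def restrict_compounds(self, keep: Sequence[str]) -> "InteractionSet":
        keep_set = set(keep)
        return InteractionSet(
            [c for c in self.compounds if c in keep_set],
            list(self.proteins),
            {(c, p) for c, p in self.positives if c in keep_set},
        )


@dataclass
class BenchmarkSeries:
    """Representative-compound subsets at increasing similarity thresholds."""

    thresholds: list[float]
    subsets: dict[float, list[str]]
    restricted: dict[float, InteractionSet]


def pair_counts(gold: InteractionSet) -> tuple[int, int, int, int]:
    """(n_compounds, n_proteins, n_positives, n_negatives) of the pair universe."""
    n_c, n_p = len(gold.compounds), len(gold.proteins)
    n_pos = len(gold.positives)
    return n_c, n_p, n_pos, n_c * n_p - n_pos


def _cluster_labels(chem_sim: SimilarityMatrix, threshold: float) -> np.ndarray:
    """Complete-linkage clusters whose within-cluster similarity is >= threshold."""
    n = len(chem_sim.ids)
    if n == 1:
        return np.ones(1, dtype=int)
    dist = 1.0 - chem_sim.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="complete")
    if threshold >= 1.0:
        # the full benchmark: every compound is its own cluster
        return np.arange(1, n + 1)
    return fcluster(z, t=1.0 - threshold, criterion="distance")


def cluster_representatives(
    chem_sim: SimilarityMatrix, threshold: float, gold: InteractionSet
) -> list[str]:
    """One representative compound per chemical cluster at the given threshold.

    The dendrogram (complete linkage on 1 - similarity) is cut at height
    1 - threshold, guaranteeing every within-cluster pair has similarity at
    least the threshold.  Each cluster is represented by the compound with
    the most gold-standard targets (ties by ascending compound ID).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    missing = set(gold.compounds) - set(chem_sim.ids)
    if missing:
        raise ValueError(f"chemical similarity does not cover compounds: {sorted(missing)[:5]}")
    sub = chem_sim.take(sorted(gold.compounds))
    labels = _cluster_labels(sub, threshold)
    n_targets = {c: len(gold.targets_of(c)) for c in sub.ids}
    reps: dict[int, str] = {}
    for cid, lab in zip(sub.ids, labels):
        lab = int(lab)
        if lab not in reps:
            reps[lab] = cid
        else:
            cur = reps[lab]
            if (-n_targets[cid], cid) < (-n_targets[cur], cur):
                reps[lab] = cid
    return sorted(reps.values())


def build_benchmark_series(
    chem_sim: SimilarityMatrix, gold: InteractionSet, thresholds: Sequence[float]
) -> BenchmarkSeries:
    """Benchmark subsets for a sorted list of similarity thresholds.

    Each threshold yields its representative compound list and the gold
    standard restricted to those compounds (the protein panel is common
    across subsets).  Subset sizes are non-decreasing in the threshold
    since all cuts come from one dendrogram.
    """
    thresholds = [float(t) for t in thresholds]
    if len(set(thresholds)) != len(thresholds):
        raise ValueError("duplicate thresholds")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    subsets: dict[float, list[str]] = {}
    restricted: dict[float, InteractionSet] = {}
    for t in thresholds:
        reps = cluster_representatives(chem_sim, t, gold)
        subsets[t] = reps
        restricted[t] = gold.restrict_compounds(reps)
    return BenchmarkSeries(thresholds, subsets, restricted)
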