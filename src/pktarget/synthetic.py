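"""Synthetic compound-target datasets with planted target-driven structure.

The generator emulates the statistical structure that expression-based
target prediction relies on — compounds perturbing the same protein leave
correlated footprints in the transcriptome — while letting the chemical and
sequence channels be dialed from fully informative to pure noise:

* every protein carries a sparse gene *signature* (5% of genes), with the
  largest loading on the gene encoding the protein itself;
* every compound draws >= 1 target proteins and its expression row is the
  sum of the target signatures, each flipped in sign with probability 1/2
  per compound (a compound may inhibit or activate its target), plus
  Gaussian noise.  The sign flips make |X| informative while raw X is not;
* descriptor vectors cluster around a per-protein center according to the
  compound's primary target; ``structure_coherence`` interpolates between
  tight clusters (1) and target-independent vectors (0);
* protein sequences form families derived from common ancestors by per-site
  mutation.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .benchmark import InteractionSet
from .io_formats import (
    LabeledMatrix,
    PairList,
    SequenceSet,
    write_fasta,
    write_matrix,
    write_pairs,
)

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "write_dataset"]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: fraction of genes in each protein's signature
SIGNATURE_DENSITY = 0.05


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a strong-signal regime at desk scale: 120 compounds,
    a 30-protein panel mapped one-to-one onto the first 30 of 600 genes,
    on average 2 targets per compound, target effects twice the noise
    standard deviation.
    """

    n_compounds: int = 120
    n_proteins: int = 30
    n_genes: int = 600
    mean_targets_per_compound: float = 2.0
    effect_size: float = 2.0
    noise_sd: float = 1.0
    structure_coherence: float = 0.5
    n_descriptors: int = 64
    sequence_length: int = 120
    family_mutation_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_proteins", "n_genes", "n_descriptors", "sequence_length"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_genes < self.n_proteins:
            raise ValueError("n_genes must be >= n_proteins (each protein maps to a distinct gene)")
        if self.mean_targets_per_compound <= 0:
            raise ValueError("mean_targets_per_compound must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.structure_coherence <= 1.0):
            raise ValueError("structure_coherence must be in [0, 1]")
        if not (0.0 <= self.family_mutation_rate <= 1.0):
            raise ValueError("family_mutation_rate must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """All four pipeline inputs plus the generating truth."""

    expression: LabeledMatrix
    descriptors: LabeledMatrix
    sequences: SequenceSet
    gold: InteractionSet
    truth: dict[str, np.ndarray]
    protein_gene_map: dict[str, str] = field(default_factory=dict)


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one complete dataset under the configured study conditions."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_sig, rng_tgt, rng_expr, rng_desc, rng_seq = (np.random.default_rng(s) for s in streams)

    compounds = _ids("cmp", config.n_compounds)
    proteins = _ids("prt", config.n_proteins)
    genes = _ids("gene", config.n_genes)
    protein_gene_map = {p: genes[i] for i, p in enumerate(proteins)}

    # per-protein sparse signatures; own gene carries the largest loading
    n_sig = max(2, round(SIGNATURE_DENSITY * config.n_genes))
    truth: dict[str, np.ndarray] = {}
    signatures = np.zeros((config.n_proteins, config.n_genes))
    for i, p in enumerate(proteins):
        others = [g for g in range(config.n_genes) if g != i]
        picked = rng_sig.choice(len(others), size=n_sig - 1, replace=False)
        # downstream genes respond at magnitudes comparable to, but never
        # exceeding, the target's own gene (unit loading): effect_size is
        # then the z-score of the target gene against unit-sd noise, and
        # the aggregate pathway footprint dominates any single gene
        mag = rng_sig.uniform(0.6, 1.0, size=n_sig - 1)
        sgn = rng_sig.choice([-1.0, 1.0], size=n_sig - 1)
        signatures[i, [others[j] for j in picked]] = mag * sgn
        signatures[i, i] = 1.0
        truth[p] = signatures[i].copy()

    # targets: 1 + Poisson(mean - 1), capped at the panel size
    n_extra = np.clip(
        rng_tgt.poisson(max(config.mean_targets_per_compound - 1.0, 0.0), size=config.n_compounds),
        0,
        config.n_proteins - 1,
    )
    target_lists: list[list[int]] = []
    positives: set[tuple[str, str]] = set()
    for ci, comp in enumerate(compounds):
        tgts = rng_tgt.choice(config.n_proteins, size=1 + int(n_extra[ci]), replace=False)
        target_lists.append([int(t) for t in tgts])
        for t in tgts:
            positives.add((comp, proteins[int(t)]))

    # expression: signed sum of target signatures plus Gaussian noise
    expr = rng_expr.normal(0.0, config.noise_sd, size=(config.n_compounds, config.n_genes))
    for ci in range(config.n_compounds):
        for t in target_lists[ci]:
            sign = 1.0 if rng_expr.random() < 0.5 else -1.0
            expr[ci] += config.effect_size * sign * signatures[t]
    expression = LabeledMatrix(compounds, genes, expr)

    # descriptors: nonnegative, clustered by primary target per structure_coherence
    centers = rng_desc.uniform(0.0, 10.0, size=(config.n_proteins, config.n_descriptors))
    own = rng_desc.uniform(0.0, 10.0, size=(config.n_compounds, config.n_descriptors))
    jitter = rng_desc.normal(0.0, 0.3, size=(config.n_compounds, config.n_descriptors))
    coh = config.structure_coherence
    desc = np.clip(coh * centers[[tl[0] for tl in target_lists]] + (1.0 - coh) * own + jitter, 0.0, None)
    for ci in range(config.n_compounds):  # guard the all-zero Tanimoto precondition
        if not desc[ci].any():
            desc[ci, 0] = 1.0
    descriptors = LabeledMatrix(compounds, _ids("desc", config.n_descriptors), desc)

    # sequences: families of ~3 proteins mutated from common ancestors
    n_families = max(1, config.n_proteins // 3)
    entries: dict[str, str] = {}
    ancestors = [
        "".join(rng_seq.choice(list(_RESIDUES), size=config.sequence_length))
        for _ in range(n_families)
    ]
    for i, p in enumerate(proteins):
        seq = list(ancestors[i % n_families])
        mutate = rng_seq.random(config.sequence_length) < config.family_mutation_rate
        for pos in np.flatnonzero(mutate):
            choices = [r for r in _RESIDUES if r != seq[pos]]
            seq[pos] = choices[int(rng_seq.integers(len(choices)))]
        entries[p] = "".join(seq)
    sequences = SequenceSet(entries)

    gold = InteractionSet(list(compounds), list(proteins), positives)
    return SyntheticDataset(expression, descriptors, sequences, gold, truth, protein_gene_map)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four pipeline inputs (plus the protein-gene map) as text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "descriptors": outdir / "descriptors.tsv",
        "sequences": outdir / "sequences.fasta",
        "interactions": outdir / "interactions.tsv",
        "protein_gene_map": outdir / "protein_gene_map.tsv",
    }
    write_matrix(ds.expression, paths["expression"])
    write_matrix(ds.descriptors, paths["descriptors"])
    write_fasta(ds.sequences, paths["sequences"])
    write_pairs(PairList([(c, p, None) for c, p in sorted(ds.gold.positives)]), paths["interactions"])
    with open(paths["protein_gene_map"], "w") as fh:
        for p, g in ds.protein_gene_map.items():
            fh.write(f"{p}\t{g}\n")
    return paths
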