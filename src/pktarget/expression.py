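"""Build the compound x gene log2 fold-change matrix from per-instance data.

The processing stage mirrors the standard treatment of perturbation
microarray compendia: one instance (treatment/control pair) is selected per
compound within a chosen cell line, fold changes are computed on the log2
scale, and multiple probes mapping to a single gene are collapsed to one
representative probe.  Normalization of raw intensities (e.g. MAS5) is
upstream of this module: inputs are already-normalized expression values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import FormatError, LabeledMatrix

__all__ = [
    "InstanceTable",
    "read_instance_table",
    "read_probe_map",
    "select_instances",
    "log2_fold_change",
    "collapse_probes",
]

_INSTANCE_COLUMNS = ["instance_id", "compound_id", "cell_line", "concentration", "batch_id"]


@dataclass
class InstanceTable:
    """Per-instance experimental annotations (one row per treatment/control pair)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _INSTANCE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"instance table missing columns: {missing}")
        if self.frame["instance_id"].duplicated().any():
            dup = self.frame.loc[self.frame["instance_id"].duplicated(), "instance_id"].iloc[0]
            raise FormatError(f"duplicate instance_id: {dup}")
        if not np.isfinite(self.frame["concentration"].to_numpy(dtype=float)).all():
            raise FormatError("non-finite concentration in instance table")

    def __len__(self) -> int:
        return len(self.frame)


def read_instance_table(path: str | Path) -> InstanceTable:
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "instance_id": int,
            "compound_id": str,
            "cell_line": str,
            "concentration": float,
            "batch_id": int,
        },
    )
    return InstanceTable(frame)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Load a 2-column TSV probe -> gene mapping."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns, got {len(fields)}")
            probe, gene = fields
            if probe in mapping:
                raise FormatError(f"line {lineno}: probe {probe!r} mapped twice")
            mapping[probe] = gene
    return mapping


def select_instances(table: InstanceTable, cell_line: str) -> list[int]:
    """Pick one instance per compound within ``cell_line``.

    Selection order: restrict to the cell line, then take the instance with
    the highest treatment concentration; concentration ties are resolved by
    the smaller batch ID, and remaining ties by the smaller instance ID.
    Compounds with no instance in the cell line yield nothing.  Returns
    instance IDs ordered by compound ID.
    """
    df = table.frame
    df = df[df["cell_line"] == cell_line]
    if df.empty:
        return []
    df = df.sort_values(
        by=["compound_id", "concentration", "batch_id", "instance_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    chosen = df.groupby("compound_id", sort=True).head(1)
    return [int(i) for i in chosen["instance_id"]]


def log2_fold_change(treatment: np.ndarray, control: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Element-wise log2(treatment / control).

    Normalized intensities are positive, so the ratio is normally taken
    raw; if any control entry is exactly zero the pseudocount is added to
    both channels to keep the ratio finite.
    """
    treatment = np.asarray(treatment, dtype=float)
    control = np.asarray(control, dtype=float)
    if treatment.shape != control.shape:
        raise ValueError(
            f"treatment and control lengths differ: {treatment.shape} vs {control.shape}"
        )
    if np.any(control == 0):
        treatment = treatment + pseudocount
        control = control + pseudocount
    return np.log2(treatment / control)


def collapse_probes(fc: LabeledMatrix, probe_map: Mapping[str, str]) -> LabeledMatrix:
    """Collapse probe columns to one representative probe per gene.

    Within each instance, probes are ranked ascending by absolute fold
    change (midranks for ties), so the most responsive probe carries the
    highest rank number.  For each gene the probe with the largest average
    rank across instances is kept and its (signed) fold-change column is
    copied verbatim.  Representative ties break toward the
    lexicographically smaller probe ID.
    """
    unmapped = [p for p in fc.col_ids if p not in probe_map]
    if unmapped:
        raise FormatError(f"probe not present in probe map: {unmapped[0]!r}")
    ranks = rankdata(np.abs(fc.values), axis=1, method="average")
    avg_rank = ranks.mean(axis=0)
    by_gene: dict[str, tuple[float, str, int]] = {}
    for j, probe in enumerate(fc.col_ids):
        gene = probe_map[probe]
        # keep the max average rank; ties -> smaller probe id
        cand = (-avg_rank[j], probe, j)
        if gene not in by_gene or cand < by_gene[gene]:
            by_gene[gene] = cand
    genes = sorted(by_gene)
    cols = [by_gene[g][2] for g in genes]
    return LabeledMatrix(list(fc.row_ids), genes, fc.values[:, cols])
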