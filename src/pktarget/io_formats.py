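"""Readers and writers for the on-disk formats the tool touches.

All tables are tab-separated (the canonical dialect of CMap annotation
files); no comma fallback is attempted, so a mis-delimited file fails
loudly instead of silently misparsing.  Matrices are serialized with 17
significant digits so that a write/read round trip is value-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "LabeledMatrix",
    "SequenceSet",
    "PairList",
    "FormatError",
    "read_matrix",
    "write_matrix",
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "write_pairs",
    "write_predictions",
]

#: residues accepted in protein sequences: the 20 standard amino acids
#: plus the common ambiguity codes.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | set("XBZ")


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class LabeledMatrix:
    """A dense real matrix with unique row and column identifiers.

    Holds the compound x gene log2 fold-change matrix X as well as the
    compound x descriptor table; rows are entities, columns are features.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} columns"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        try:
            return self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"unknown row identifier: {row_id!r}") from None

    def col_index(self, col_id: str) -> int:
        try:
            return self.col_ids.index(col_id)
        except ValueError:
            raise KeyError(f"unknown column identifier: {col_id!r}") from None

    def take_rows(self, row_ids: Sequence[str]) -> "LabeledMatrix":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = [pos[r] for r in row_ids]
        return LabeledMatrix(list(row_ids), list(self.col_ids), self.values[idx, :])

    def take_cols(self, col_ids: Sequence[str]) -> "LabeledMatrix":
        pos = {c: i for i, c in enumerate(self.col_ids)}
        idx = [pos[c] for c in col_ids]
        return LabeledMatrix(list(self.row_ids), list(col_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


@dataclass
class SequenceSet:
    """Ordered mapping of protein identifiers to amino-acid strings."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, seq in self.entries.items():
            if not seq:
                raise FormatError(f"empty sequence for {pid!r}")
            bad = set(seq) - AMINO_ACIDS
            if bad:
                raise FormatError(
                    f"sequence {pid!r} contains invalid residues: "
                    f"{''.join(sorted(bad))}"
                )

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, pid: str) -> str:
        return self.entries[pid]

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        return SequenceSet({i: self.entries[i] for i in ids})


@dataclass
class PairList:
    """Compound-protein pairs with an optional activity flag per row."""

    pairs: list[tuple[str, str, Optional[str]]] = field(default_factory=list)

    def interactions(self) -> list[tuple[str, str]]:
        return [(c, p) for c, p, _ in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def read_matrix(path: str | Path, orientation: str = "rows-are-compounds") -> LabeledMatrix:
    """Load a labeled TSV matrix (first row = column IDs, first column = row IDs)."""
    if orientation != "rows-are-compounds":
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    _check_unique(col_ids, "column")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = [str(r) for r in df.index]
    _check_unique(row_ids, "row")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j in range(df.shape[1]):
        # numpy's parser round-trips %.17g exactly (pandas' to_numeric does not)
        try:
            col = raw[:, j].astype(np.float64)
        except (ValueError, TypeError):
            col = np.full(df.shape[0], np.nan)
            for i in range(df.shape[0]):
                try:
                    col[i] = np.float64(raw[i, j])
                except (ValueError, TypeError):
                    break
        bad = ~np.isfinite(col)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"non-numeric or missing value at row {row_ids[i]!r}, "
                f"column {col_ids[j]!r}: {raw[i, j]!r}"
            )
        values[:, j] = col
    return LabeledMatrix(row_ids, col_ids, values)


def write_matrix(matrix: LabeledMatrix, path: str | Path) -> None:
    """Write a labeled matrix as TSV with 17 significant digits."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label="")


def read_fasta(path: str | Path) -> SequenceSet:
    """Load a FASTA file; the ID is the first whitespace token of the header."""
    entries: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in entries:
            raise FormatError(f"duplicate sequence identifier: {pid!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence record: {pid!r}")
        entries[pid] = seq
    return SequenceSet(entries)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in seqs.entries.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pairs(path: str | Path, active_flag: Optional[str] = None) -> PairList:
    """Load a 2- or 3-column TSV pair list.

    When ``active_flag`` is given, rows whose third column differs from it
    are dropped before deduplication (the flag filter used to restrict
    database interactions to those annotated "active").  Duplicate
    (compound, protein) rows collapse to their first occurrence.
    """
    pairs: list[tuple[str, str, Optional[str]]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"line {lineno}: expected 2 or 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            comp, prot = fields[0], fields[1]
            flag = fields[2] if len(fields) == 3 else None
            if not comp or not prot:
                raise FormatError(f"line {lineno}: empty identifier")
            if active_flag is not None and flag != active_flag:
                continue
            if (comp, prot) in seen:
                continue
            seen.add((comp, prot))
            pairs.append((comp, prot, flag))
    return PairList(pairs)


def write_pairs(pairs: PairList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for comp, prot, flag in pairs.pairs:
            if flag is None:
                fh.write(f"{comp}\t{prot}\n")
            else:
                fh.write(f"{comp}\t{prot}\t{flag}\n")


def write_predictions(
    compound_ids: Sequence[str],
    protein_ids: Sequence[str],
    scores: np.ndarray,
    path: str | Path,
) -> None:
    """Write (compound, protein, score) rows sorted by descending score.

    Ties are broken by (compound-id, protein-id) so output order is stable.
    """
    scores = np.asarray(scores, dtype=float)
    rows = [
        (compound_ids[i], protein_ids[j], scores[i, j])
        for i in range(len(compound_ids))
        for j in range(len(protein_ids))
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("compound\tprotein\tscore\n")
        for comp, prot, s in rows:
            fh.write(f"{comp}\t{prot}\t{s:.17g}\n")
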