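"""Pairwise kernel regression (PKR) over compound-protein pairs.

The model scores a pair (x', y') as

    f(x', y') = sum_i sum_j beta_ij k_compound(x_i, x') k_protein(y_j, y')

i.e. kernel ridge regression whose Gram matrix is the Kronecker product
K_compound (x) K_protein over all n_x * n_y training pairs.  The weights
solve

    (K_c (x) K_p + lambda I) vec(B) = vec(Y)

with Y the 0/1 interaction label matrix.  Training never materializes the
n_x*n_y square system: with eigendecompositions K_c = U S U^T and
K_p = V T V^T the solution is B = U [ (U^T Y V) / (s_i t_j + lambda) ] V^T,
which costs two small symmetric eigendecompositions instead of a cubic
solve in the number of pairs.  This factorization is exactly the dense
solve, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .direct import ScoreMatrix
from .similarity import CrossSimilarityMatrix, SimilarityMatrix

__all__ = ["PKRModel", "make_psd", "train", "predict", "label_matrix",
           "save_model", "load_model", "KERNEL_KINDS"]

KERNEL_KINDS = ("transcriptomic", "chemogenomic", "integrative")


@dataclass
class PKRModel:
    """Trained PKR weights plus the IDs needed to align kernels at predict time."""

    train_compound_ids: list[str]
    train_protein_ids: list[str]
    beta: np.ndarray
    lam: float
    kernel_kind: str = "transcriptomic"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.train_compound_ids), len(self.train_protein_ids)):
            raise ValueError("beta shape does not match ID lists")
        if not np.isfinite(self.beta).all():
            raise ValueError("non-finite beta")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


def make_psd(k: SimilarityMatrix, tol: float = 1e-8) -> SimilarityMatrix:
    """Project a symmetric kernel onto the PSD cone by clipping eigenvalues.

    The normalized Smith-Waterman kernel is not guaranteed positive
    semidefinite; negative eigenvalues are clipped to zero and the matrix
    reconstructed.  A kernel already PSD within ``tol`` is returned
    unchanged.  Clipping (rather than shifting the diagonal) keeps the unit
    diagonal as close to 1 as possible.
    """
    v = k.values
    if not np.allclose(v, v.T, atol=1e-8, rtol=0):
        raise ValueError("make_psd requires a symmetric matrix")
    w, q = np.linalg.eigh(v)
    if w.min() >= -tol:
        return k
    w = np.clip(w, 0.0, None)
    rebuilt = (q * w) @ q.T
    rebuilt = (rebuilt + rebuilt.T) / 2.0
    return SimilarityMatrix(list(k.ids), rebuilt)


def label_matrix(
    positives: set[tuple[str, str]],
    compound_ids: Sequence[str],
    protein_ids: Sequence[str],
) -> np.ndarray:
    """0/1 matrix over compound_ids x protein_ids; 1 iff the pair is a positive."""
    y = np.zeros((len(compound_ids), len(protein_ids)))
    ppos = {p: j for j, p in enumerate(protein_ids)}
    cpos = {c: i for i, c in enumerate(compound_ids)}
    for c, p in positives:
        i, j = cpos.get(c), ppos.get(p)
        if i is not None and j is not None:
            y[i, j] = 1.0
    return y


def train(
    k_compound: SimilarityMatrix,
    k_protein: SimilarityMatrix,
    labels: np.ndarray,
    lam: float = 1.0,
    kernel_kind: str = "transcriptomic",
) -> PKRModel:
    """Fit PKR weights by Kronecker-factorized kernel ridge regression."""
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    labels = np.asarray(labels, dtype=float)
    n_x, n_y = len(k_compound.ids), len(k_protein.ids)
    if labels.shape != (n_x, n_y):
        raise ValueError(
            f"label matrix shape {labels.shape} does not match kernels ({n_x}, {n_y})"
        )
    s, u = np.linalg.eigh(k_compound.values)
    t, v = np.linalg.eigh(k_protein.values)
    if s.min() < -1e-6 or t.min() < -1e-6:
        raise ValueError(
            "kernel has a significantly negative eigenvalue; apply make_psd first"
        )
    s = np.clip(s, 0.0, None)
    t = np.clip(t, 0.0, None)
    m = u.T @ labels @ v
    beta = u @ (m / (np.outer(s, t) + lam)) @ v.T
    return PKRModel(list(k_compound.ids), list(k_protein.ids), beta, lam, kernel_kind)


def predict(
    model: PKRModel,
    k_compound_cross: CrossSimilarityMatrix,
    k_protein: SimilarityMatrix | CrossSimilarityMatrix,
) -> ScoreMatrix:
    """Score test compounds against a protein panel.

    ``k_compound_cross`` holds test x training compound similarities; the
    protein kernel may be the training square kernel (panel = training
    proteins) or a cross kernel of training proteins against a new panel.
    """
    if k_compound_cross.reference_ids != model.train_compound_ids:
        raise ValueError("compound cross-kernel reference IDs do not match the model")
    if isinstance(k_protein, SimilarityMatrix):
        if k_protein.ids != model.train_protein_ids:
            raise ValueError("protein kernel IDs do not match the model")
        kp = k_protein.values
        panel = list(k_protein.ids)
    else:
        if k_protein.query_ids != model.train_protein_ids:
            raise ValueError("protein cross-kernel query IDs must be the model's training proteins")
        kp = k_protein.values
        panel = list(k_protein.reference_ids)
    scores = k_compound_cross.values @ model.beta @ kp
    return ScoreMatrix(list(k_compound_cross.query_ids), panel, scores)


def save_model(model: PKRModel, path: str | Path) -> None:
    """Serialize a model as a small text file: header lines + a beta TSV block."""
    with open(path, "w") as fh:
        fh.write("#pkr-model\tv1\n")
        fh.write(f"#kernel_kind\t{model.kernel_kind}\n")
        fh.write(f"#lambda\t{model.lam:.17g}\n")
        fh.write("beta\t" + "\t".join(model.train_protein_ids) + "\n")
        for i, cid in enumerate(model.train_compound_ids):
            row = "\t".join(f"{x:.17g}" for x in model.beta[i])
            fh.write(f"{cid}\t{row}\n")


def load_model(path: str | Path) -> PKRModel:
    with open(path) as fh:
        magic = fh.readline().rstrip("\n").split("\t")
        if magic[:1] != ["#pkr-model"]:
            raise ValueError(f"{path}: not a PKR model file")
        kind = fh.readline().rstrip("\n").split("\t")[1]
        lam = float(fh.readline().rstrip("\n").split("\t")[1])
        header = fh.readline().rstrip("\n").split("\t")
        proteins = header[1:]
        compounds: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            compounds.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
    return PKRModel(compounds, proteins, np.array(rows), lam, kind)
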