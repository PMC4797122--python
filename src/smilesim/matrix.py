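"""Labeled similarity matrices: assembly, kernel repair, composites, I/O.

The :class:`SimilarityMatrix` is the exchange format between the
compound kernels and the interaction predictor.  ``make_kernel``
repairs an arbitrary similarity matrix into a valid (symmetric,
positive-definite) kernel by symmetrizing and applying a minimal
diagonal shift, which preserves off-diagonal similarities exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .prep import CompoundRecord

if TYPE_CHECKING:  # pragma: no cover
    from .registry import KernelSpec

logger = logging.getLogger(__name__)

PSD_EPS = 1e-9


@dataclass
class SimilarityMatrix:
    """Square labeled matrix of pairwise scores plus provenance metadata."""

    labels: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reorder(self, labels: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy with rows/columns permuted to ``labels``."""
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(list(labels), self.values[np.ix_(idx, idx)], dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_matrix(
    corpus: Sequence[CompoundRecord],
    kernel: "KernelSpec",
) -> SimilarityMatrix:
    """Evaluate a kernel on every compound pair.

    The upper triangle (including the diagonal) is computed once and
    mirrored, which guarantees bit-exact symmetry for symmetric kernels
    and halves the cost.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    pair = kernel.prepare(corpus)
    n = len(corpus)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            try:
                values[i, j] = pair(corpus[i], corpus[j])
            except Exception as exc:
                raise RuntimeError(
                    f"kernel {kernel.name!r} failed on pair "
                    f"({corpus[i].id!r}, {corpus[j].id!r}): {exc}"
                ) from exc
            values[j, i] = values[i, j]
    meta = {"kernel": kernel.name, **kernel.params, "n_compounds": n}
    return SimilarityMatrix([r.id for r in corpus], values, meta)


def make_kernel(S: SimilarityMatrix, eps: float = PSD_EPS) -> SimilarityMatrix:
    """Repair a similarity matrix into a valid kernel.

    Symmetrize as ``(S + S^T)/2``, then if the smallest eigenvalue is
    below ``eps`` shift the whole diagonal up by the deficit, so the
    output has all eigenvalues >= eps.  Off-diagonal entries are
    untouched.  Idempotent up to ``eps``.
    """
    v = S.values
    if not np.isfinite(v).all():
        raise ValueError("similarity matrix contains non-finite entries")
    sym = (v + v.T) / 2.0
    lam_min = float(np.linalg.eigvalsh(sym)[0])
    shift = max(0.0, eps - lam_min)
    if shift > 0.0:
        sym = sym + shift * np.eye(len(S.labels))
    meta = {**S.meta, "psd_shift": shift}
    return SimilarityMatrix(list(S.labels), sym, meta)


def composite(
    S_simcomp: SimilarityMatrix, S_f: SimilarityMatrix, lam: float = 0.5
) -> SimilarityMatrix:
    """Composite kernel ``lam * S_simcomp + (1 - lam) * S_f``.

    With the default ``lam=0.5`` this is the unweighted average of a 2D
    graph-based similarity matrix and a SMILES-based one.  Mixing
    happens on raw similarities, before any kernel repair.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if S_simcomp.labels != S_f.labels:
        for a, b in zip(S_simcomp.labels, S_f.labels):
            if a != b:
                raise ValueError(f"label mismatch: {a!r} vs {b!r}")
        raise ValueError("label lists differ in length")
    values = lam * S_simcomp.values + (1.0 - lam) * S_f.values
    meta = {
        "kernel": "composite",
        "lambda": lam,
        "left": S_simcomp.meta.get("kernel"),
        "right": S_f.meta.get("kernel"),
    }
    return SimilarityMatrix(list(S_simcomp.labels), values, meta)


def write_similarity_tsv(
    path: str | Path, S: SimilarityMatrix, precision: int = 6
) -> None:
    """Write the labeled TSV dialect; metadata goes into '#' header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in S.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("\t" + "\t".join(S.labels) + "\n")
        for label, row in zip(S.labels, S.values):
            cells = "\t".join(f"{x:.{precision}g}" for x in row)
            fh.write(f"{label}\t{cells}\n")


def read_similarity_tsv(path: str | Path) -> SimilarityMatrix:
    """Read a labeled square TSV matrix (tolerates \\r\\n line endings)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    labels = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if labels != cols:
        raise ValueError(f"{path}: row and column labels differ")
    return SimilarityMatrix(labels, df.to_numpy(dtype=np.float64), {"source": str(path)})
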