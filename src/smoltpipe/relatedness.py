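"""Pedigree-based additive genetic relationship matrix A and its inverse.

A is built by the tabular method (Emik & Terrill): for individual i with
parents s and d,

    A[i, j] = (A[s, j] + A[d, j]) / 2        for every earlier j,
    A[i, i] = 1 + A[s, d] / 2,

with an unknown parent contributing zero.  The inverse is assembled
directly from Henderson's rules, with inbreeding coefficients (diagonal
of A minus one) entering the Mendelian-sampling variances, so the result
is exact for inbred pedigrees as well.

The matrices are dense: the intended scale (hundreds of fish, a few
thousand at most) does not justify sparse machinery, though a sparse
triplet export is provided for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, PedigreeError


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix aligned with a pedigree.

    ``kind`` is ``"A"`` for the relationship matrix itself or ``"Ainv"``
    for its inverse (the precision structure of the breeding-value
    random effect).
    """

    values: np.ndarray
    ids: list[str]
    kind: str  # "A" | "Ainv"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("relationship matrix must be square and match ids")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_triplets(self, tol: float = 0.0) -> pd.DataFrame:
        """Sparse COO export of the upper triangle (|value| > tol)."""
        i, j = np.nonzero(np.triu(np.abs(self.values) > tol))
        return pd.DataFrame(
            {
                "row": [self.ids[k] for k in i],
                "col": [self.ids[k] for k in j],
                "value": self.values[i, j],
            }
        )


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F (diagonal of A minus one)."""
    return np.diag(additive_matrix(ped).values) - 1.0


def additive_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix A by the tabular method."""
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += A[s, :i]
        if d != UNKNOWN:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
    return RelationshipMatrix(A, list(ped.ids), "A")


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Inverse of A assembled by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of individual i is

        d_i = 1 - 0.25 * sum over known parents p of (1 + F_p),

    i.e. 1, 0.75 - F_p/4 or 0.5 - (F_s + F_d)/4 for zero, one or two
    known parents.  Each individual contributes w = 1/d_i to the
    (i, parents) block.
    """
    ped.validate()
    n = ped.n
    F = inbreeding(ped)
    Ainv = np.zeros((n, n))
    for i in range(n):
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        d_i = 1.0 - 0.25 * sum(1.0 + F[p] for p in parents)
        if d_i <= 0:  # cannot happen for a valid pedigree
            raise PedigreeError(f"non-positive Mendelian variance at {ped.ids[i]!r}")
        w = 1.0 / d_i
        Ainv[i, i] += w
        for p in parents:
            Ainv[i, p] -= 0.5 * w
            Ainv[p, i] -= 0.5 * w
        for p in parents:
            for q in parents:
                Ainv[p, q] += 0.25 * w
    return RelationshipMatrix(Ainv, list(ped.ids), "Ainv")
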