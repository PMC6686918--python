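"""Relationship matrices for autotetraploids.

Three matrices drive the GBLUP stage: the pedigree-based additive
relationship ``A`` from a kinship recursion under tetrasomic (bivalent)
inheritance with an optional double-reduction rate; the genomic
relationship ``K = W W' / (tr(W W') / n)`` from the column-centered
dosage matrix ``W``; and the blend ``K* = w K + (1 - w) A`` (default
``w = 0.99``) which guarantees an invertible matrix for mixed-model
equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from polygs.dosage import DosageMatrix
from polygs.simpop import Pedigree, _is_na

__all__ = [
    "RelationshipMatrix",
    "build_a_tetraploid",
    "build_k",
    "blend",
]


@dataclass
class RelationshipMatrix:
    """Square symmetric relationship matrix with id labels and provenance."""

    values: np.ndarray
    ids: pd.Index
    provenance: str  # pedigree | genomic | blended
    ploidy: int = 4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = pd.Index(self.ids, name="individual")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids) -> "RelationshipMatrix":
        pos = self.ids.get_indexer(ids)
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"ids not in matrix: {missing[:5]}")
        return RelationshipMatrix(
            self.values[np.ix_(pos, pos)], pd.Index(ids), self.provenance, self.ploidy
        )

    def cross(self, row_ids, col_ids) -> np.ndarray:
        rpos = self.ids.get_indexer(row_ids)
        cpos = self.ids.get_indexer(col_ids)
        if (rpos < 0).any() or (cpos < 0).any():
            raise KeyError("ids not in matrix")
        return self.values[np.ix_(rpos, cpos)]


def build_a_tetraploid(
    pedigree: Pedigree, double_reduction: float = 0.0
) -> RelationshipMatrix:
    """Pedigree additive relationship under tetrasomic inheritance.

    Kinship coefficients are propagated down the (topologically ordered)
    pedigree: an offspring's kinship with any earlier individual is the
    parent-average, its inbreeding combines the two gametes' identity
    probabilities (each ``alpha + (1 - alpha) F_parent`` with ``alpha``
    the double-reduction rate, since with probability ``alpha`` a gamete
    carries two copies of one parental allele) with the parents' mutual
    kinship.  ``A = 4 * kinship`` so a non-inbred founder has diagonal
    1; unknown parents act as unrelated non-inbred founders.
    """
    if not 0.0 <= double_reduction <= 1.0:
        raise ValueError("double_reduction must lie in [0, 1]")
    rec = pedigree.records
    if (rec["ploidy"] != 4).any():
        raise ValueError("build_a_tetraploid requires ploidy-4 pedigree records")
    ids = rec["id"].tolist()
    pos = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    theta = np.zeros((n, n))
    F = np.zeros(n)
    alpha = double_reduction

    dam_idx = [None if _is_na(d) else pos[d] for d in rec["dam"]]
    sire_idx = [None if _is_na(s) else pos[s] for s in rec["sire"]]

    for o in range(n):
        d, s = dam_idx[o], sire_idx[o]
        if d is None and s is None:
            F[o] = 0.0
            theta[o, o] = 0.25  # (1 + 3F)/4
            continue
        # kinship with every earlier individual: parent average
        for x in range(o):
            td = theta[d, x] if d is not None else 0.0
            ts = theta[s, x] if s is not None else 0.0
            theta[o, x] = theta[x, o] = 0.5 * (td + ts)
        # inbreeding: both alleles from one gamete (1/6 each) or across (2/3)
        gam_d = alpha + (1.0 - alpha) * (F[d] if d is not None else 0.0)
        gam_s = alpha + (1.0 - alpha) * (F[s] if s is not None else 0.0)
        t_ds = theta[d, s] if (d is not None and s is not None) else 0.0
        F[o] = (gam_d + gam_s) / 6.0 + (2.0 / 3.0) * t_ds
        theta[o, o] = (1.0 + 3.0 * F[o]) / 4.0

    A = 4.0 * theta
    return RelationshipMatrix(A, pd.Index(ids), "pedigree", ploidy=4)


def build_k(dosages: DosageMatrix, centering: str = "mean") -> RelationshipMatrix:
    """Genomic relationship K = W W' / (tr(W W') / n) from dosages.

    ``W`` is the dosage matrix with each marker column centered — by its
    observed mean (default) or by ``ploidy * p`` with ``p`` the
    reference-allele frequency (``centering='frequency'``; identical
    population-level expectation, VanRaden-style).  The trace
    normalization fixes ``tr(K) = n``.  Monomorphic markers contribute
    zero columns; an all-monomorphic panel has no signal and errors.
    """
    X = dosages.complete_array()
    if centering == "mean":
        W = X - X.mean(axis=0)
    elif centering == "frequency":
        p = X.mean(axis=0) / dosages.ploidy
        W = X - dosages.ploidy * p  # same as mean centering, explicit form
    else:
        raise ValueError("centering must be 'mean' or 'frequency'")
    WWt = W @ W.T
    tr = np.trace(WWt)
    if tr <= 0:
        raise ValueError("all markers monomorphic: tr(WW') = 0")
    K = WWt / (tr / dosages.n_individuals)
    K = 0.5 * (K + K.T)
    return RelationshipMatrix(K, dosages.individuals, "genomic", dosages.ploidy)


def blend(
    K: RelationshipMatrix, A: RelationshipMatrix, w: float = 0.99
) -> RelationshipMatrix:
    """K* = w K + (1 - w) A, positive definite when A is and w < 1."""
    if not 0.0 < w <= 1.0:
        raise ValueError("blend weight must lie in (0, 1]")
    if len(K.ids) != len(A.ids) or not (K.ids == A.ids).all():
        raise ValueError("K and A must cover the same individuals in the same order")
    return RelationshipMatrix(
        w * K.values + (1.0 - w) * A.values, K.ids, "blended", K.ploidy
    )
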