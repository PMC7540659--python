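"""Pedigree handling and the additive (numerator) relationship matrix.

The matrix ``A`` built here is the genetic covariance kernel shared by all
mixed models in the package: ``Var(a) = A * sigma_a^2`` for a vector of
breeding values, with ``A[i, i] = 1 + F_i`` (``F_i`` the inbreeding
coefficient) and off-diagonals equal to twice the kinship coefficient.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PedigreeError",
    "PedigreeTable",
    "RelationshipMatrix",
    "build_A",
    "subset_A",
]

#: sentinel values accepted for an unknown parent in input records
UNKNOWN_PARENT = {None, "", "0", 0, "NA", "na", "nan"}


class PedigreeError(ValueError):
    """Raised for cyclic, inconsistent or unresolvable pedigrees."""


def _is_unknown(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return value in UNKNOWN_PARENT


@dataclass(frozen=True)
class PedigreeTable:
    """Topologically ordered pedigree: parents always precede offspring.

    ``sire``/``dam`` hold ``None`` where the parent is unknown.  Use
    :meth:`from_records` to build one from arbitrarily ordered input; the
    constructor itself trusts the ordering it is given.
    """

    animal: tuple
    sire: tuple
    dam: tuple
    index: Mapping[Hashable, int] = field(repr=False, default=None)

    def __post_init__(self):
        if self.index is None:
            object.__setattr__(
                self, "index", {a: i for i, a in enumerate(self.animal)}
            )
        if len(self.index) != len(self.animal):
            raise PedigreeError("duplicate animal ids in pedigree")
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            for parent in (s, d):
                if parent is None:
                    continue
                j = self.index.get(parent)
                if j is None:
                    raise PedigreeError(
                        f"parent {parent!r} of {self.animal[i]!r} has no own record"
                    )
                if j >= i:
                    raise PedigreeError(
                        f"pedigree not topologically ordered at {self.animal[i]!r}"
                    )

    def __len__(self) -> int:
        return len(self.animal)

    @classmethod
    def from_records(
        cls,
        animal: Sequence,
        sire: Sequence,
        dam: Sequence,
        *,
        add_missing_parents: bool = True,
    ) -> "PedigreeTable":
        """Build an ordered table from unordered (animal, sire, dam) triples.

        Parents that appear only in the sire/dam columns get implicit founder
        records when ``add_missing_parents`` (the default).  A cycle (an
        animal among its own ancestors) raises :class:`PedigreeError`.
        """
        parents: dict = {}
        for a, s, d in zip(animal, sire, dam):
            if _is_unknown(a):
                raise PedigreeError("blank animal id in pedigree")
            if a in parents:
                raise PedigreeError(f"duplicate pedigree record for {a!r}")
            s = None if _is_unknown(s) else s
            d = None if _is_unknown(d) else d
            if a in (s, d):
                raise PedigreeError(f"animal {a!r} recorded as its own parent")
            parents[a] = (s, d)
        if add_missing_parents:
            for s, d in list(parents.values()):
                for p in (s, d):
                    if p is not None and p not in parents:
                        parents[p] = (None, None)
        sorter = graphlib.TopologicalSorter(
            {a: [p for p in ps if p is not None] for a, ps in parents.items()}
        )
        try:
            order = list(sorter.static_order())
        except graphlib.CycleError as exc:
            raise PedigreeError(f"cyclic pedigree: {exc.args[1]}") from exc
        return cls(
            animal=tuple(order),
            sire=tuple(parents[a][0] for a in order),
            dam=tuple(parents[a][1] for a in order),
        )


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator relationship matrix over an ordered set of animals."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficients ``F = diag(A) - 1``."""
        return np.diag(self.values) - 1.0

    def __len__(self) -> int:
        return len(self.ids)

    def to_tsv(self, path) -> None:
        """Debug dump: square TSV with ids as header and index."""
        import pandas as pd

        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t"
        )


def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Tabular (recursive) numerator relationship matrix with inbreeding.

    For animal ``i`` with parents ``s, d`` (ordered before ``i``):
    ``A[i, j] = 0.5 * (A[s, j] + A[d, j])`` for ``j < i`` (missing parents
    contribute 0) and ``A[i, i] = 1 + 0.5 * A[s, d]`` (1 when either parent
    is unknown).
    """
    n = len(ped)
    A = np.zeros((n, n))
    sidx = [ped.index[s] if s is not None else -1 for s in ped.sire]
    didx = [ped.index[d] if d is not None else -1 for d in ped.dam]
    for i in range(n):
        s, d = sidx[i], didx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=tuple(ped.animal), values=A)


def subset_A(R: RelationshipMatrix, ids: Iterable) -> RelationshipMatrix:
    """Principal submatrix of ``A`` in the requested id order."""
    ids = tuple(ids)
    lookup = {a: i for i, a in enumerate(R.ids)}
    try:
        idx = np.array([lookup[a] for a in ids], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown animal id {exc.args[0]!r}") from exc
    return RelationshipMatrix(ids=ids, values=R.values[np.ix_(idx, idx)])
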