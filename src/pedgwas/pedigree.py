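"""Pedigree parsing and the numerator relationship matrix.

The polygenic term of the scan model is ``u ~ N(0, A * sigma_g^2)`` where
``A`` is the pedigree-based numerator relationship matrix (twice the kinship
matrix).  This module reads animal/sire/dam pedigrees, validates and
topologically orders them, and builds ``A`` with the tabular (recursive)
method including inbreeding.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "read_pedigree",
    "build_A",
    "submatrix_A",
    "prune_to_ancestors",
]

DEFAULT_UNKNOWN_CODES = ("0", "NA", "", ".")


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycle, duplicate id, unknown id)."""


@dataclass(frozen=True)
class Pedigree:
    """An augmented, topologically sorted animal-sire-dam pedigree.

    ``records`` lists ``(animal, sire, dam)`` with ``None`` for an unknown
    parent; parents always precede their offspring.  ``generation_count`` is
    the maximum ancestor depth (founders are depth 0).
    """

    records: tuple[tuple[str, str | None, str | None], ...]
    generation_count: int = field(default=0)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        return {a: (s, d) for a, s, d in self.records}

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(
        cls, records: list[tuple[str | None, str | None, str | None]]
    ) -> "Pedigree":
        """Validate, augment phantom parents as founders, topologically sort.

        Raises
        ------
        PedigreeError
            On duplicate animal ids or cyclic ancestry (e.g. self-ancestry).
        """
        seen: dict[str, tuple[str | None, str | None]] = {}
        for animal, sire, dam in records:
            if animal is None:
                raise PedigreeError("animal id missing in pedigree record")
            if animal in seen:
                raise PedigreeError(f"duplicate animal id: {animal!r}")
            seen[animal] = (sire, dam)
        # phantom parents (appear only as sire/dam) become founders
        for sire, dam in list(seen.values()):
            for parent in (sire, dam):
                if parent is not None and parent not in seen:
                    seen[parent] = (None, None)
        graph = {
            a: [p for p in ps if p is not None] for a, ps in seen.items()
        }
        try:
            order = list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            cycle = exc.args[1]
            raise PedigreeError(
                f"pedigree cycle detected involving id {cycle[0]!r}: "
                f"{' -> '.join(map(str, cycle))}"
            ) from exc
        depth: dict[str, int] = {}
        for a in order:
            s, d = seen[a]
            depth[a] = max(
                (depth[p] + 1 for p in (s, d) if p is not None), default=0
            )
        recs = tuple((a, *seen[a]) for a in order)
        return cls(records=recs, generation_count=max(depth.values(), default=0))


def read_pedigree(
    path: str | Path,
    unknown_codes: tuple[str, ...] = DEFAULT_UNKNOWN_CODES,
) -> Pedigree:
    """Read a 3-column ``animal,sire,dam`` CSV (with header) into a Pedigree.

    Parents whose id is in ``unknown_codes`` are treated as unknown; parents
    that never appear as animals are appended as founders.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise PedigreeError(
            f"pedigree file {path} must have 3 columns (animal,sire,dam)"
        )
    df = df.iloc[:, :3]
    unknown = set(unknown_codes)

    def clean(v: str) -> str | None:
        v = v.strip()
        return None if v in unknown else v

    records = [
        (clean(a), clean(s), clean(d))
        for a, s, d in df.itertuples(index=False, name=None)
    ]
    for a, _, _ in records:
        if a is None:
            raise PedigreeError("animal id equals the unknown-parent code")
    return Pedigree.from_records(records)


@dataclass
class RelationshipMatrix:
    """Additive (numerator) relationships for an ordered set of animals."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        return submatrix_A(self, ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix via the tabular method, with inbreeding.

    ``a(i,i) = 1 + 0.5 * a(sire(i), dam(i))`` and, for ``j`` preceding ``i``,
    ``a(i,j) = 0.5 * (a(j, sire(i)) + a(j, dam(i)))``; unknown parents
    contribute zero (unrelated, non-inbred founders).
    """
    ids = ped.ids
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (animal, sire, dam) in enumerate(ped.records):
        s = idx[sire] if sire is not None else -1
        d = idx[dam] if dam is not None else -1
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(ids=list(ids), values=A)


def submatrix_A(A: RelationshipMatrix, ids: list[str]) -> RelationshipMatrix:
    """Restrict/reorder ``A`` to ``ids``; values are unchanged."""
    missing = [a for a in ids if a not in A._index]
    if missing:
        raise PedigreeError(
            f"ids not present in relationship matrix: {missing[:10]}"
        )
    take = np.array([A._index[a] for a in ids], dtype=int)
    return RelationshipMatrix(ids=list(ids), values=A.values[np.ix_(take, take)])


def prune_to_ancestors(ped: Pedigree, ids: list[str]) -> Pedigree:
    """Prune the pedigree to ``ids`` and all their ancestors.

    The relationship matrix among ``ids`` built on the pruned pedigree is
    identical to the corresponding block built on the full pedigree, so the
    phenotyped subset can be handled without the full (potentially much
    larger) pedigree.
    """
    parents = ped.parents
    missing = [a for a in ids if a not in parents]
    if missing:
        raise PedigreeError(f"ids not present in pedigree: {missing[:10]}")
    keep: set[str] = set()
    stack = list(ids)
    while stack:
        a = stack.pop()
        if a in keep:
            continue
        keep.add(a)
        stack.extend(p for p in parents[a] if p is not None)
    records = [
        (a, s, d) for a, s, d in ped.records if a in keep
    ]
    return Pedigree.from_records(records)
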