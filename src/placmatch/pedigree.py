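"""Pedigree kinship and inbreeding coefficients by Malecot recursion.

The kinship (coancestry) coefficient f(i, j) is the probability that a
random allele from i and a random allele from j are identical by descent;
an individual's inbreeding coefficient F equals the kinship of its parents.
The recursion is the standard one:

    f(i, i) = 0.5 * (1 + f(sire_i, dam_i))
    f(i, j) = 0.5 * (f(sire_i, j) + f(dam_i, j))   recursing on the
              individual that cannot be an ancestor of the other
    f(., UNKNOWN) = 0

Missing parents are treated as unique unrelated founders (contribution 0).
A topological order over the pedigree is computed once so the recursion
always descends in age rank and terminates; results are memoised.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import PedigreeError, SchemaError
from .genotype_io import PairRecord

__all__ = ["Pedigree", "inbreeding_report"]

Parents = tuple[str | None, str | None]


class Pedigree:
    """Acyclic sire/dam mapping with memoised kinship and inbreeding."""

    def __init__(self, parents: Mapping[str, Parents]):
        self._parents: dict[str, Parents] = {}
        for ind, (sire, dam) in parents.items():
            self._parents[ind] = (sire or None, dam or None)
        # referenced parents not listed themselves become founders
        for sire, dam in list(self._parents.values()):
            for p in (sire, dam):
                if p is not None and p not in self._parents:
                    self._parents[p] = (None, None)
        self._rank = self._toposort()
        self._kin_cache: dict[tuple[str, str], float] = {}

    def _toposort(self) -> dict[str, int]:
        # Kahn's algorithm, parents before offspring; leftovers indicate a cycle
        children: dict[str, list[str]] = {i: [] for i in self._parents}
        indeg = {i: 0 for i in self._parents}
        for ind, (sire, dam) in self._parents.items():
            for p in (sire, dam):
                if p is not None:
                    children[p].append(ind)
                    indeg[ind] += 1
        queue = sorted(i for i, d in indeg.items() if d == 0)
        rank: dict[str, int] = {}
        while queue:
            nxt = queue.pop(0)
            rank[nxt] = len(rank)
            for ch in children[nxt]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(rank) != len(self._parents):
            cycle = sorted(set(self._parents) - set(rank))
            raise PedigreeError(f"pedigree contains a cycle involving {cycle}")
        return rank

    @property
    def ids(self) -> list[str]:
        return sorted(self._parents, key=self._rank.__getitem__)

    def __contains__(self, ind: str) -> bool:
        return ind in self._parents

    def parents(self, ind: str) -> Parents:
        try:
            return self._parents[ind]
        except KeyError:
            raise PedigreeError(f"unknown individual {ind!r}") from None

    # -- kinship ------------------------------------------------------------

    def kinship(self, i: str | None, j: str | None) -> float:
        """Malecot kinship f(i, j); UNKNOWN (None) contributes 0."""
        if i is None or j is None:
            return 0.0
        for ind in (i, j):
            if ind not in self._parents:
                raise PedigreeError(f"unknown individual {ind!r}")
        return self._kinship(i, j)

    def _kinship(self, i: str | None, j: str | None) -> float:
        if i is None or j is None:
            return 0.0
        key = (i, j) if i <= j else (j, i)
        cached = self._kin_cache.get(key)
        if cached is not None:
            return cached
        if i == j:
            sire, dam = self._parents[i]
            value = 0.5 * (1.0 + self._kinship(sire, dam))
        else:
            # recurse on the younger individual (cannot be an ancestor of the other)
            if self._rank[i] < self._rank[j]:
                i, j = j, i
            sire, dam = self._parents[i]
            value = 0.5 * (self._kinship(sire, j) + self._kinship(dam, j))
        self._kin_cache[key] = value
        return value

    def inbreeding(self, ind: str) -> float:
        """F = kinship of the parents; 0 when either parent is unknown."""
        sire, dam = self.parents(ind)
        if sire is None or dam is None:
            return 0.0
        return self.kinship(sire, dam)

    def kinship_matrix(self, ids: Sequence[str] | None = None) -> pd.DataFrame:
        ids = list(ids) if ids is not None else self.ids
        data = [[self.kinship(i, j) for j in ids] for i in ids]
        return pd.DataFrame(data, index=ids, columns=ids)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "Pedigree":
        """Read a pedigree CSV with columns id, sire, dam (empty = unknown)."""
        path = Path(path)
        parents: dict[str, Parents] = {}
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"id", "sire", "dam"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise SchemaError(f"{path}: expected columns {sorted(required)}")
            for row in reader:
                parents[row["id"].strip()] = (
                    row["sire"].strip() or None,
                    row["dam"].strip() or None,
                )
        return cls(parents)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "sire", "dam"])
            for ind in self.ids:
                sire, dam = self._parents[ind]
                writer.writerow([ind, sire or "", dam or ""])


def inbreeding_report(
    pedigree: Pedigree, pairs: Iterable[PairRecord]
) -> pd.DataFrame:
    """Per-individual inbreeding coefficients for the pairs' mares and foals.

    Returns columns individual, role (mare/foal), group, F. Individuals
    absent from the pedigree are treated as founders (F = 0).
    """
    rows = []
    for pair in pairs:
        for role, ind in (("mare", pair.mare_id), ("foal", pair.foal_id)):
            f = pedigree.inbreeding(ind) if ind in pedigree else 0.0
            rows.append({"individual": ind, "role": role, "group": pair.group, "F": f})
    return pd.DataFrame(rows)
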