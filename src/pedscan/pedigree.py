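"""Pedigree representation, PED file I/O and kinship coefficients.

A pedigree is a directed acyclic graph of individuals; founders have no
parents inside the pedigree, every non-founder has exactly two.  Affection
status follows the usual PED convention (2 = affected, 1 = unaffected,
0/-9 = unknown).  The ``genotyped`` flag records which members contributed
marker data; it is not part of the 6-column PED dialect and is supplied
separately (default: everyone).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "kinship_matrix",
    "index_family",
]

_SEX_FROM_PED = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_AFF_FROM_PED = {"2": "yes", "1": "no", "0": "unknown", "-9": "unknown"}
_AFF_TO_PED = {"yes": "2", "no": "1", "unknown": "0"}


class PedigreeError(ValueError):
    """Structural or reference error in a pedigree."""


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affected: str = "unknown"
    genotyped: bool = True

    def __post_init__(self) -> None:
        if self.sex not in _SEX_TO_PED:
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.id}")
        if self.affected not in _AFF_TO_PED:
            raise PedigreeError(f"invalid affection {self.affected!r} for {self.id}")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"{self.id}: non-founders need both parents, founders neither"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A validated single-family pedigree.

    Validation enforces: parent references resolve within the pedigree;
    no individual is its own ancestor; the two parents of a non-founder
    have opposite (or unknown) sex.
    """

    def __init__(self, members: Iterable[Individual], family_id: str = "FAM1"):
        self.family_id = family_id
        self.members: list[Individual] = list(members)
        self.by_id: dict[str, Individual] = {}
        for m in self.members:
            if m.id in self.by_id:
                raise PedigreeError(f"duplicate individual id {m.id}")
            self.by_id[m.id] = m
        self._validate()

    def _validate(self) -> None:
        for m in self.members:
            if m.is_founder:
                continue
            for pid in (m.father_id, m.mother_id):
                if pid not in self.by_id:
                    raise PedigreeError(f"{m.id}: unresolved parent id {pid!r}")
            if m.father_id == m.id or m.mother_id == m.id:
                raise PedigreeError(f"{m.id} lists itself as a parent")
            f, mo = self.by_id[m.father_id], self.by_id[m.mother_id]
            if "unknown" not in (f.sex, mo.sex) and f.sex == mo.sex:
                raise PedigreeError(f"{m.id}: parents {f.id}/{mo.id} have equal sex")
        # cycle detection via ancestor walk
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(i: str) -> None:
            if state.get(i) == 1:
                return
            if state.get(i) == 0:
                raise PedigreeError(f"parentage cycle involving {i}")
            state[i] = 0
            ind = self.by_id[i]
            if not ind.is_founder:
                visit(ind.father_id)
                visit(ind.mother_id)
            state[i] = 1

        for m in self.members:
            visit(m.id)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.topological_order() if not m.is_founder]

    @property
    def affected_ids(self) -> list[str]:
        return [m.id for m in self.members if m.affected == "yes"]

    @property
    def genotyped_ids(self) -> list[str]:
        return [m.id for m in self.members if m.genotyped]

    def topological_order(self) -> list[Individual]:
        """Members ordered so that every parent precedes its children."""
        order: list[Individual] = []
        seen: set[str] = set()

        def visit(i: str) -> None:
            if i in seen:
                return
            ind = self.by_id[i]
            if not ind.is_founder:
                visit(ind.father_id)
                visit(ind.mother_id)
            seen.add(i)
            order.append(ind)

        for m in self.members:
            visit(m.id)
        return order

    def with_genotyped(self, ids: Iterable[str]) -> "Pedigree":
        """Copy of the pedigree with the genotyped flag set on ``ids`` only."""
        idset = set(ids)
        unknown = idset - set(self.by_id)
        if unknown:
            raise PedigreeError(f"unknown genotyped ids: {sorted(unknown)}")
        return Pedigree(
            [replace(m, genotyped=m.id in idset) for m in self.members],
            family_id=self.family_id,
        )


def read_pedigree(path: str | Path, genotyped: Iterable[str] | None = None) -> Pedigree:
    """Read a 6-column whitespace-separated PED file into a Pedigree.

    Columns: family, individual, father, mother, sex, phenotype; ``0``
    denotes a missing parent.  All rows must carry the same family id.
    ``genotyped``, when given, restricts the genotyped flag to those ids.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"PED line has {len(fields)} fields, expected 6: {line!r}")
        rows.append(fields[:6])
    if not rows:
        raise PedigreeError(f"empty PED file: {path}")
    fams = {r[0] for r in rows}
    if len(fams) > 1:
        raise PedigreeError(f"multiple family ids in one PED file: {sorted(fams)}")
    members = []
    for fam, iid, fid, mid, sex, pheno in rows:
        members.append(
            Individual(
                id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_FROM_PED.get(sex, "unknown"),
                affected=_AFF_FROM_PED.get(pheno, "unknown"),
            )
        )
    ped = Pedigree(members, family_id=rows[0][0])
    if genotyped is not None:
        ped = ped.with_genotyped(genotyped)
    return ped


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write the 6-column PED representation of a pedigree."""
    with open(path, "w") as fh:
        for m in ped.members:
            fh.write(
                "\t".join(
                    [
                        ped.family_id,
                        m.id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_TO_PED[m.sex],
                        _AFF_TO_PED[m.affected],
                    ]
                )
                + "\n"
            )


def kinship_matrix(ped: Pedigree) -> pd.DataFrame:
    """Kinship coefficients phi(i, j) for all members of a pedigree.

    Founders are assumed non-inbred and mutually unrelated.  The classic
    recursion processes individuals parents-first:

        phi(i, i) = 1/2 (1 + phi(father_i, mother_i))
        phi(i, j) = 1/2 (phi(father_i, j) + phi(mother_i, j))   j already placed

    Returns a symmetric DataFrame indexed by individual id.
    """
    order = [m.id for m in ped.topological_order()]
    idx = {i: k for k, i in enumerate(order)}
    n = len(order)
    K = np.zeros((n, n))
    for i in order:
        ind = ped.by_id[i]
        ii = idx[i]
        if ind.is_founder:
            K[ii, ii] = 0.5
        else:
            fi, mi = idx[ind.father_id], idx[ind.mother_id]
            K[ii, ii] = 0.5 * (1.0 + K[fi, mi])
            for j in order[:order.index(i)]:
                jj = idx[j]
                K[ii, jj] = K[jj, ii] = 0.5 * (K[fi, jj] + K[mi, jj])
    return pd.DataFrame(K, index=order, columns=order)


def index_family(genotyped: Sequence[str] = ("I.2", "II.2", "II.3", "II.4", "II.5", "III.3", "III.5")) -> Pedigree:
    """The three-generation multiplex family used throughout this package.

    Five affected members across two generations: four affected full sibs
    (II.2-II.5, children of founders I.1 x I.2) and one affected grandchild
    (III.5, child of II.5 and a married-in founder).  III.3 is an unaffected
    genotyped grandchild (child of II.2 and a married-in founder).  Twelve
    meiosis bits in total, so the inheritance-vector space has 4096 states.
    """
    members = [
        Individual("I.1", sex="male", affected="no"),
        Individual("I.2", sex="female", affected="no"),
        Individual("II.2", "I.1", "I.2", sex="male", affected="yes"),
        Individual("II.3", "I.1", "I.2", sex="female", affected="yes"),
        Individual("II.4", "I.1", "I.2", sex="male", affected="yes"),
        Individual("II.5", "I.1", "I.2", sex="female", affected="yes"),
        Individual("II.6", sex="male", affected="no"),   # married-in, spouse of II.5
        Individual("II.7", sex="female", affected="no"),  # married-in, spouse of II.2
        Individual("III.3", "II.2", "II.7", sex="male", affected="no"),
        Individual("III.5", "II.6", "II.5", sex="female", affected="yes"),
    ]
    return Pedigree(members, family_id="INDEX").with_genotyped(genotyped)
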