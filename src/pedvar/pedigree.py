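"""Pedigree representation, PED file IO and analysis-role assignment.

A cohort for recessive-model segregation filtering has four analysis roles:
obligate carrier parents (unaffected parents of an affected offspring, which
under full penetrance must be heterozygous), affected cases (homozygous for
the causal allele), unaffected siblings (anything but homozygous alternate)
and unrelated controls (homozygous reference).  Everyone else in the pedigree
is carried along as ``unused`` and places no constraint on a variant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Role(enum.Enum):
    """Analysis role of a sample under the segregation model."""

    OBLIGATE_CARRIER_PARENT = "obligate_carrier_parent"
    AFFECTED_CASE = "affected_case"
    UNAFFECTED_SIBLING = "unaffected_sibling"
    UNRELATED_CONTROL = "unrelated_control"
    UNUSED = "unused"


_SEX_CODE = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_CODE = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}
_AFF_TO_CODE = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent pedigree input."""


class Pedigree:
    """An ordered collection of individuals with parent links.

    Iteration order is insertion order, which makes file round trips and
    report output deterministic.
    """

    def __init__(self, individuals: Iterable[Individual] = ()) -> None:
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            self.add(ind)

    def add(self, individual: Individual) -> None:
        if individual.id in self._members:
            raise PedigreeError(f"duplicate individual id: {individual.id!r}")
        self._members[individual.id] = individual

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._members

    def __getitem__(self, ind_id: str) -> Individual:
        return self._members[ind_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._members == other._members

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def offspring(self) -> list[Individual]:
        """Individuals with at least one recorded parent."""
        return [i for i in self if not i.is_founder]

    def litters(self) -> dict[tuple[str | None, str | None], list[Individual]]:
        """Group offspring by their (sire, dam) pair, in insertion order."""
        out: dict[tuple[str | None, str | None], list[Individual]] = {}
        for ind in self.offspring():
            out.setdefault((ind.sire_id, ind.dam_id), []).append(ind)
        return out

    def children_of(self, parent_id: str) -> list[Individual]:
        return [i for i in self if parent_id in (i.sire_id, i.dam_id)]

    def affected(self) -> list[Individual]:
        return [i for i in self if i.affection is Affection.AFFECTED]

    def parents_of_affected(self) -> list[Individual]:
        """Distinct individuals that are a sire or dam of an affected member."""
        seen: dict[str, Individual] = {}
        for case in self.affected():
            for pid in (case.sire_id, case.dam_id):
                if pid is not None and pid in self._members:
                    seen.setdefault(pid, self._members[pid])
        return list(seen.values())

    def ancestors_of(self, ind_id: str) -> set[str]:
        """All ancestor ids reachable through recorded parent links."""
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            cur = stack.pop()
            ind = self._members.get(cur)
            if ind is None:
                continue
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file.

    Columns: family, id, sire, dam, sex (1=male, 2=female, other=unknown),
    phenotype (1=unaffected, 2=affected, 0/-9=unknown).  A parent code of
    ``0`` means the parent is unrecorded.  Lines starting with ``#`` are
    ignored.  Every non-zero parent id must itself appear as a row.
    """
    path = Path(path)
    ped = Pedigree()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >=6 columns, got {len(cols)}"
                )
            fam, ind_id, sire, dam, sex, pheno = cols[:6]
            ped.add(
                Individual(
                    id=ind_id,
                    family_id=fam,
                    sire_id=None if sire == "0" else sire,
                    dam_id=None if dam == "0" else dam,
                    sex=_SEX_CODE.get(sex, Sex.UNKNOWN),
                    affection=_AFF_CODE.get(pheno, Affection.UNKNOWN),
                )
            )
    for ind in ped:
        for pid in (ind.sire_id, ind.dam_id):
            if pid is not None and pid not in ped:
                raise PedigreeError(
                    f"individual {ind.id!r} references unknown parent {pid!r}"
                )
    return ped


def write_ped(pedigree: Pedigree, path: str | Path) -> Path:
    """Write ``pedigree`` in the 6-column PED dialect read by :func:`read_ped`."""
    path = Path(path)
    lines = ["#family\tid\tsire\tdam\tsex\tphenotype"]
    for ind in pedigree:
        lines.append(
            "\t".join(
                [
                    ind.family_id,
                    ind.id,
                    ind.sire_id or "0",
                    ind.dam_id or "0",
                    _SEX_TO_CODE[ind.sex],
                    _AFF_TO_CODE[ind.affection],
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class RoleAssignment:
    """Mapping from sample id to analysis role.

    Control ids may be external to the pedigree (e.g. unrelated dogs of a
    different breed sequenced in another project).
    """

    roles: dict[str, Role] = field(default_factory=dict)

    def __getitem__(self, sample_id: str) -> Role:
        return self.roles.get(sample_id, Role.UNUSED)

    def samples_with_role(self, role: Role) -> list[str]:
        return [s for s, r in self.roles.items() if r is role]

    def count(self, role: Role) -> int:
        return sum(1 for r in self.roles.values() if r is role)

    def constrained_samples(self) -> list[str]:
        return [s for s, r in self.roles.items() if r is not Role.UNUSED]


def assign_roles(
    pedigree: Pedigree,
    sequenced_ids: Iterable[str],
    control_ids: Iterable[str],
) -> RoleAssignment:
    """Derive analysis roles from the pedigree and the sequencing design.

    Sequenced affected individuals become cases; both their parents become
    obligate carriers; sequenced unaffected individuals sharing both parents
    with a sequenced case become unaffected siblings.  Controls must not
    belong to any case family.
    """
    sequenced = list(dict.fromkeys(sequenced_ids))
    controls = list(dict.fromkeys(control_ids))
    unknown = [s for s in sequenced if s not in pedigree]
    if unknown:
        raise PedigreeError(f"sequenced ids not in pedigree: {unknown}")

    roles: dict[str, Role] = {}
    cases = [pedigree[s] for s in sequenced
             if pedigree[s].affection is Affection.AFFECTED]
    case_parent_pairs = set()
    case_families = set()
    for case in cases:
        if case.sire_id is None or case.dam_id is None:
            raise PedigreeError(
                f"sequenced affected {case.id!r} has a missing parent; "
                "obligate carriers cannot be assigned"
            )
        roles[case.id] = Role.AFFECTED_CASE
        roles[case.sire_id] = Role.OBLIGATE_CARRIER_PARENT
        roles[case.dam_id] = Role.OBLIGATE_CARRIER_PARENT
        case_parent_pairs.add((case.sire_id, case.dam_id))
        case_families.add(case.family_id)

    for sid in sequenced:
        ind = pedigree[sid]
        if sid in roles:
            continue
        if (
            ind.affection is Affection.UNAFFECTED
            and (ind.sire_id, ind.dam_id) in case_parent_pairs
        ):
            roles[sid] = Role.UNAFFECTED_SIBLING

    overlap = [
        c for c in controls
        if c in pedigree and pedigree[c].family_id in case_families
    ]
    if overlap:
        raise PedigreeError(f"control ids belong to a case family: {overlap}")
    for cid in controls:
        roles[cid] = Role.UNRELATED_CONTROL
    return RoleAssignment(roles)


def read_roles_tsv(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a cohort-design TSV (columns: id, sequenced, control).

    Returns (sequenced_ids, control_ids).  Control ids may be external to
    the pedigree.
    """
    sequenced: list[str] = []
    controls: list[str] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        try:
            i_id = header.index("id")
            i_seq = header.index("sequenced")
            i_ctl = header.index("control")
        except ValueError:
            raise PedigreeError(
                f"{path}: roles TSV needs columns id, sequenced, control"
            )
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[i_seq] == "1":
                sequenced.append(cols[i_id])
            if cols[i_ctl] == "1":
                controls.append(cols[i_id])
    return sequenced, controls


def validate_pedigree(pedigree: Pedigree) -> list[str]:
    """Return a list of consistency violations (empty when the pedigree is clean).

    Checks: parent links are cycle-free, sires are male (or unknown sex), dams
    female (or unknown), and every affected offspring has both parents
    recorded.
    """
    violations: list[str] = []
    for ind in pedigree:
        if ind.id in pedigree.ancestors_of(ind.id):
            violations.append(f"cycle: {ind.id} is its own ancestor")
        for pid, want in ((ind.sire_id, Sex.MALE), (ind.dam_id, Sex.FEMALE)):
            if pid is not None and pid in pedigree:
                psex = pedigree[pid].sex
                if psex not in (want, Sex.UNKNOWN):
                    violations.append(
                        f"sex: parent {pid} of {ind.id} recorded as {psex.value}, "
                        f"expected {want.value}"
                    )
        if ind.affection is Affection.AFFECTED and (
            ind.sire_id is None or ind.dam_id is None
        ):
            violations.append(f"parents: affected {ind.id} lacks a recorded parent")
    return violations
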