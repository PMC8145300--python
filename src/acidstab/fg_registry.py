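"""Registry of reactive functional groups and their assignment to molecules.

A functional group is a SMARTS-defined reactive motif with a precedence rank.
Compound groups (e.g. the 1,2-diol) rank above their constituents (alcohol),
so a vicinal diol is assigned as one diol copy rather than two alcohols.
Copy counts feed the multi-copy half-life correction in
:func:`acidstab.kinetics.half_life_multi`.

The shipped :func:`default_registry` is a documented illustrative set with
placeholder kinetics, exercisable without any external measured-rate table;
a full user-supplied table is loadable via :func:`load_groups`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem

from acidstab.chem_io import MoleculeRecord

REACTION_CLASSES = ("solvolysis", "sulfonation")


@dataclass(frozen=True)
class FunctionalGroup:
    """A reactive motif: SMARTS pattern, precedence rank, reaction class."""

    group_id: str
    name: str
    smarts: str
    priority: int
    reaction_class: str = "solvolysis"

    def __post_init__(self) -> None:
        if self.reaction_class not in REACTION_CLASSES:
            raise ValueError(
                f"group {self.group_id!r}: reaction_class must be one of {REACTION_CLASSES}"
            )


@dataclass(frozen=True)
class GroupAssignment:
    """One group matched in one molecule with its copy count."""

    group_id: str
    n_copies: int
    atom_sets: tuple[frozenset[int], ...]
    reaction_class: str


@dataclass
class MatchResult:
    molecule_id: str
    assignments: list[GroupAssignment]
    status: str  # "matched" | "no_reactive_groups"

    def group_ids(self) -> list[str]:
        return [a.group_id for a in self.assignments]


class GroupRegistry:
    """Queryable collection of functional groups with compiled SMARTS."""

    def __init__(self, groups: Iterable[FunctionalGroup] = ()):
        self._groups: dict[str, FunctionalGroup] = {}
        self._queries: dict[str, Chem.Mol] = {}
        self._order: list[str] = []
        for g in groups:
            self.add(g)

    def add(self, group: FunctionalGroup) -> None:
        if group.group_id in self._groups:
            raise ValueError(f"duplicate group id {group.group_id!r}")
        query = Chem.MolFromSmarts(group.smarts)
        if query is None:
            raise ValueError(f"group {group.group_id!r}: invalid SMARTS {group.smarts!r}")
        self._groups[group.group_id] = group
        self._queries[group.group_id] = query
        self._order.append(group.group_id)

    def get(self, group_id: str) -> FunctionalGroup:
        return self._groups[group_id]

    def query(self, group_id: str) -> Chem.Mol:
        return self._queries[group_id]

    def remove(self, group_id: str) -> None:
        del self._groups[group_id]
        del self._queries[group_id]
        self._order.remove(group_id)

    def __contains__(self, group_id: str) -> bool:
        return group_id in self._groups

    def __len__(self) -> int:
        return len(self._groups)

    def __iter__(self) -> Iterator[FunctionalGroup]:
        return (self._groups[gid] for gid in self._order)

    def registration_rank(self, group_id: str) -> int:
        return self._order.index(group_id)


def register_groups(definitions: Iterable[FunctionalGroup]) -> GroupRegistry:
    """Build a registry, validating ids and SMARTS (errors name the offender)."""
    return GroupRegistry(definitions)


# Illustrative default set.  Priorities: compound groups above constituents;
# kinetics attached to these ids by synthdata are placeholders, not literature
# values.
DEFAULT_GROUPS: tuple[FunctionalGroup, ...] = (
    FunctionalGroup("diol_1_2", "1,2-diol", "[OX2H][CX4][CX4][OX2H]", 100),
    FunctionalGroup("phosphate_ester", "phosphate ester", "[PX4](=[OX1])[OX2][#6]", 90),
    FunctionalGroup("tms_ether", "trimethylsilyl ether", "[OX2][Si]([CH3])([CH3])[CH3]", 88),
    FunctionalGroup("silyl_ether", "silyl ether", "[OX2][Si]", 85),
    FunctionalGroup("carboxylic_acid", "carboxylic acid", "[CX3](=O)[OX2H1]", 70),
    FunctionalGroup("ester", "carboxylic ester", "[CX3](=O)[OX2H0][#6]", 70),
    FunctionalGroup("amide", "carboxamide", "[CX3](=O)[NX3]", 70),
    FunctionalGroup("aldehyde", "aldehyde", "[CX3H1]=[OX1]", 60),
    FunctionalGroup("ketone", "ketone", "[#6][CX3](=[OX1])[#6]", 60),
    FunctionalGroup("nitrile", "nitrile", "[CX2]#[NX1]", 50),
    FunctionalGroup("alkyne", "alkyne", "[CX2]#[CX2]", 50),
    FunctionalGroup("alkene", "alkene", "[CX3]=[CX3]", 45),
    FunctionalGroup("thiol", "thiol", "[SX2H]", 40),
    FunctionalGroup("amine", "amine", "[NX3;!$([NX3]=[OX1])]", 35),
    FunctionalGroup("phenol", "phenol", "[OX2H]c", 30),
    FunctionalGroup("alcohol", "alcohol", "[OX2H][CX4]", 30),
    FunctionalGroup("ether", "ether", "[OX2H0]([#6])[#6]", 20),
    FunctionalGroup("aromatic_ch", "aromatic C-H (sulfonation target)", "[cH]", 10, "sulfonation"),
)


def default_registry() -> GroupRegistry:
    return GroupRegistry(DEFAULT_GROUPS)


def resolve_overlaps(
    raw_matches: Sequence[tuple[FunctionalGroup, frozenset[int]]],
    registry: GroupRegistry,
) -> list[GroupAssignment]:
    """Greedy precedence resolution of raw substructure matches.

    Matches are processed in descending priority (ties by registration order,
    then by sorted atom indices, i.e. left-to-right in the canonical atom
    ranking); a match is kept only if its atom set is disjoint from every
    atom already consumed.  Identical (group, atom-set) matches are collapsed
    beforehand.
    """
    uniq: dict[tuple[str, frozenset[int]], FunctionalGroup] = {}
    for group, atoms in raw_matches:
        uniq.setdefault((group.group_id, atoms), group)
    ordered = sorted(
        uniq.items(),
        key=lambda kv: (
            -kv[1].priority,
            registry.registration_rank(kv[1].group_id),
            sorted(kv[0][1]),
        ),
    )
    consumed: set[int] = set()
    kept: dict[str, list[frozenset[int]]] = {}
    for (gid, atoms), group in ordered:
        if atoms & consumed:
            continue
        consumed |= atoms
        kept.setdefault(gid, []).append(atoms)
    out = []
    for gid in sorted(kept, key=lambda g: -registry.get(g).priority):
        sets = tuple(sorted(kept[gid], key=sorted))
        out.append(
            GroupAssignment(
                group_id=gid,
                n_copies=len(sets),
                atom_sets=sets,
                reaction_class=registry.get(gid).reaction_class,
            )
        )
    return out


def match_groups(record: MoleculeRecord, registry: GroupRegistry) -> MatchResult:
    """Assign functional groups (with copy counts) to a parsed molecule.

    Matching runs on the canonical form so that copy counts are invariant
    under input atom renumbering.
    """
    if not record.ok:
        raise ValueError(f"cannot match rejected record {record.id!r}: {record.reason}")
    mol = Chem.MolFromSmiles(record.canonical)
    raw: list[tuple[FunctionalGroup, frozenset[int]]] = []
    for group in registry:
        for match in mol.GetSubstructMatches(registry.query(group.group_id), uniquify=True):
            raw.append((group, frozenset(match)))
    assignments = resolve_overlaps(raw, registry)
    status = "matched" if assignments else "no_reactive_groups"
    return MatchResult(molecule_id=record.id, assignments=assignments, status=status)


def load_groups(path: str | Path) -> GroupRegistry:
    """Load group definitions from CSV or JSON.

    CSV columns / JSON keys: ``group_id,name,smarts,priority,reaction_class``.
    """
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    groups = [
        FunctionalGroup(
            group_id=r["group_id"],
            name=r.get("name", r["group_id"]),
            smarts=r["smarts"],
            priority=int(r["priority"]),
            reaction_class=r.get("reaction_class", "solvolysis") or "solvolysis",
        )
        for r in rows
    ]
    return register_groups(groups)


def save_groups(registry: GroupRegistry, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_id", "name", "smarts", "priority", "reaction_class"])
        for g in registry:
            writer.writerow([g.group_id, g.name, g.smarts, g.priority, g.reaction_class])
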