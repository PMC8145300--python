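"""Molecule parsing, canonicalization, and dataset I/O.

All downstream stages consume :class:`MoleculeRecord`, a lightweight graph
view of an RDKit molecule.  Parsing never raises on bad input: invalid SMILES
produce a record with ``parse_status="rejected"`` and a reason, so that a
dataset load can account for every input line.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: bond order vocabulary used throughout the package
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_BOND_TYPE_TO_NAME = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

_NAME_TO_BOND_TYPE = {v: k for k, v in _BOND_TYPE_TO_NAME.items()}

#: component policies for multi-component (dotted) SMILES
PARSE_POLICIES = ("largest", "keep", "reject")


@dataclass
class MoleculeRecord:
    """Parsed molecular graph.

    atoms are ``(element, formal_charge, implicit_h)`` triples; bonds are
    ``(i, j, order)`` with ``order`` one of :data:`BOND_ORDERS`.
    """

    id: str
    source_smiles: str
    atoms: list[tuple[str, int, int]] = field(default_factory=list)
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    canonical: str | None = None
    parse_status: str = "ok"
    reason: str | None = None
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def ok(self) -> bool:
        return self.parse_status == "ok"

    @property
    def n_heavy(self) -> int:
        return sum(1 for el, _, _ in self.atoms if el != "H")

    def elements(self) -> set[str]:
        """Element symbols present, counting implicit hydrogens."""
        out = {el for el, _, _ in self.atoms}
        if any(h > 0 for _, _, h in self.atoms):
            out.add("H")
        return out


def _rejected(mol_id: str, smiles: str, reason: str) -> MoleculeRecord:
    return MoleculeRecord(id=mol_id, source_smiles=smiles, parse_status="rejected", reason=reason)


def record_from_mol(mol: Chem.Mol, mol_id: str, source_smiles: str) -> MoleculeRecord:
    """Build a record from a sanitized RDKit molecule."""
    atoms = [
        (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_TYPE_TO_NAME[b.GetBondType()])
        for b in mol.GetBonds()
    ]
    return MoleculeRecord(
        id=mol_id,
        source_smiles=source_smiles,
        atoms=atoms,
        bonds=bonds,
        canonical=Chem.MolToSmiles(mol),
        mol=mol,
    )


def parse_molecule(smiles: str, mol_id: str = "", policy: str = "largest") -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Parameters
    ----------
    smiles:
        Input SMILES text.
    mol_id:
        Identifier attached to the record (defaults to the SMILES itself).
    policy:
        How to treat multi-component input: ``"largest"`` keeps the covalent
        component with the most heavy atoms (tie broken by input order),
        ``"keep"`` retains all components, ``"reject"`` rejects the input.

    Invalid input yields a rejected record, never an exception.
    """
    if policy not in PARSE_POLICIES:
        raise ValueError(f"unknown parse policy {policy!r}")
    mol_id = mol_id or smiles.strip()
    if not smiles or not smiles.strip():
        return _rejected(mol_id, smiles, "empty SMILES")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        return _rejected(mol_id, smiles, "unparseable SMILES")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # valence violations, kekulization failures, ...
        return _rejected(mol_id, smiles, f"sanitization failed: {exc}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        if policy == "reject":
            return _rejected(mol_id, smiles, f"multi-component input ({len(frags)} parts)")
        if policy == "largest":
            mol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return record_from_mol(mol, mol_id, smiles)


def canonical_form(record: MoleculeRecord) -> str:
    """Canonical SMILES of a successfully parsed record.

    Equal structures map to equal text regardless of input atom ordering.
    """
    if not record.ok or record.canonical is None:
        raise ValueError(f"record {record.id!r} was rejected: {record.reason}")
    return record.canonical


def dedup_records(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Drop records whose canonical form was already seen (first wins)."""
    seen: set[str] = set()
    out = []
    for r in records:
        key = r.canonical if r.ok else f"__rejected__{r.id}"
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def load_dataset(
    path: str | Path,
    format: str = "smiles",
    policy: str = "largest",
) -> tuple[list[MoleculeRecord], list[tuple[int, str]]]:
    """Load a molecule dataset from a plain-text file.

    ``format="smiles"``: one SMILES per line, optional tab/comma-separated id
    column, lines starting with ``#`` ignored.  ``format="csv"``: header with
    ``id`` and ``smiles`` columns.

    Returns ``(records, rejections)`` where rejections is a list of
    ``(line_number, reason)``.  Every non-comment input line is accounted for
    as exactly one record; records that fail to parse are returned with
    ``parse_status="rejected"`` *and* logged in the rejection list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    rejections: list[tuple[int, str]] = []
    if format == "smiles":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split(",")
                smiles = parts[0].strip()
                mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"line{lineno}"
                rec = parse_molecule(smiles, mol_id=mol_id, policy=policy)
                records.append(rec)
                if not rec.ok:
                    rejections.append((lineno, rec.reason or "rejected"))
    elif format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: CSV must have 'id' and 'smiles' columns")
            for lineno, row in enumerate(reader, start=2):
                rec = parse_molecule(row["smiles"], mol_id=row["id"], policy=policy)
                records.append(rec)
                if not rec.ok:
                    rejections.append((lineno, rec.reason or "rejected"))
    else:
        raise ValueError(f"unknown format {format!r}")
    return records, rejections


def save_dataset(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as CSV (``id,smiles``); canonical SMILES for parsed records."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles"])
        for r in records:
            writer.writerow([r.id, r.canonical if r.ok else r.source_smiles])


def save_rejections(rejections: Iterable[tuple[int, str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["line", "reason"])
        writer.writerows(rejections)


def mol_from_graph(
    elements: Sequence[str],
    bonds: Sequence[tuple[int, int, int]],
) -> Chem.Mol:
    """Build a sanitized RDKit molecule from (element list, integer-order bonds).

    Bond orders are 1, 2 or 3.  Hydrogens are implicit fill-to-valence.
    Raises on valence violations.
    """
    order_types = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    rw = Chem.RWMol()
    for el in elements:
        rw.AddAtom(Chem.Atom(el))
    for i, j, o in bonds:
        rw.AddBond(int(i), int(j), order_types[o])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol
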