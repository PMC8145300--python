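"""Chemical-diversity statistics over stable subsets of a dataset.

Two statistics: the mean number of distinct bond types among molecules that
are stable at a threshold (a rough index of structural diversity -- alkanes
have two bond types, C-H and C-C; amides five), and the per-element fraction
of element-containing molecules that are stable.

A bond type is an (unordered element pair, bond order) pair, including bonds
to implicit hydrogens.  Aromatic bonds are their own bond order by default,
which keeps the count independent of the Kekule structure chosen by the
parser; pass ``aromatic_distinct=False`` to type a Kekulized form instead.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem

from acidstab.chem_io import MoleculeRecord, record_from_mol
from acidstab.stability import StabilityResult

BondType = tuple[str, str, str]


def _typed(e1: str, e2: str, order: str) -> BondType:
    a, b = sorted((e1, e2))
    return (a, b, order)


def bond_type_set(record: MoleculeRecord, aromatic_distinct: bool = True) -> set[BondType]:
    """Distinct bond types of a molecule, counting implicit-hydrogen bonds."""
    if not record.ok:
        raise ValueError(f"record {record.id!r} was rejected: {record.reason}")
    if not aromatic_distinct:
        mol = Chem.MolFromSmiles(record.canonical)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        record = record_from_mol(mol, record.id, record.source_smiles)
    out: set[BondType] = set()
    for i, j, order in record.bonds:
        out.add(_typed(record.atoms[i][0], record.atoms[j][0], order))
    for element, _, n_h in record.atoms:
        if n_h > 0:
            out.add(_typed(element, "H", "single"))
    return out


def countable_bonds(record: MoleculeRecord) -> int:
    """Number of bonds between non-hydrogen atoms (cyclohexane and benzene: 6)."""
    if not record.ok:
        raise ValueError(f"record {record.id!r} was rejected: {record.reason}")
    return sum(
        1
        for i, j, _ in record.bonds
        if record.atoms[i][0] != "H" and record.atoms[j][0] != "H"
    )


def _stable_ids_by_altitude(
    results: Iterable[StabilityResult], threshold_s: float
) -> dict[float, set[str]]:
    out: dict[float, set[str]] = {}
    for r in results:
        if r.altitude_km is None:
            continue
        out.setdefault(r.altitude_km, set())
        if r.ok and r.half_life_s >= threshold_s:
            out[r.altitude_km].add(r.molecule_id)
    return dict(sorted(out.items()))


def mean_bond_diversity(
    records: Sequence[MoleculeRecord],
    results: Iterable[StabilityResult],
    threshold_s: float,
    aromatic_distinct: bool = True,
) -> dict[float, float]:
    """Per-altitude mean bond-type count of molecules stable at a threshold.

    Altitudes where no molecule qualifies are absent from the result.
    """
    sizes = {
        r.id: len(bond_type_set(r, aromatic_distinct=aromatic_distinct))
        for r in records
        if r.ok
    }
    out: dict[float, float] = {}
    for alt, stable_ids in _stable_ids_by_altitude(results, threshold_s).items():
        vals = [sizes[i] for i in stable_ids if i in sizes]
        if vals:
            out[alt] = sum(vals) / len(vals)
    return out


def element_stability_fractions(
    datasets: Sequence[tuple[Sequence[MoleculeRecord], Sequence[StabilityResult]]],
    threshold_s: float,
    weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per (element, altitude) fraction of element-containing molecules that are stable.

    Each dataset contributes the fraction of its matched, element-containing
    molecules with t >= threshold; datasets are combined as a weighted mean
    with weights defaulting to dataset sizes (counts of successfully parsed
    molecules).  Elements absent from every dataset are absent rows.
    Returns a DataFrame indexed by element with altitude columns.
    """
    if weights is None:
        weights = [sum(1 for r in recs if r.ok) for recs, _ in datasets]
    if len(weights) != len(datasets):
        raise ValueError("one weight per dataset required")

    per_dataset: list[dict[tuple[str, float], float]] = []
    elements: set[str] = set()
    altitudes: set[float] = set()
    for recs, results in datasets:
        elems_of = {r.id: r.elements() for r in recs if r.ok}
        matched: dict[float, list[StabilityResult]] = {}
        for r in results:
            if r.altitude_km is None or not r.ok:
                continue
            matched.setdefault(r.altitude_km, []).append(r)
        fracs: dict[tuple[str, float], float] = {}
        for alt, rs in matched.items():
            altitudes.add(alt)
            by_elem_total: dict[str, int] = {}
            by_elem_stable: dict[str, int] = {}
            for r in rs:
                for el in elems_of.get(r.molecule_id, ()):
                    by_elem_total[el] = by_elem_total.get(el, 0) + 1
                    if r.half_life_s >= threshold_s:
                        by_elem_stable[el] = by_elem_stable.get(el, 0) + 1
            for el, total in by_elem_total.items():
                elements.add(el)
                fracs[(el, alt)] = by_elem_stable.get(el, 0) / total
        per_dataset.append(fracs)

    alts = sorted(altitudes)
    rows = {}
    for el in sorted(elements):
        row = []
        for alt in alts:
            num = 0.0
            den = 0.0
            for fracs, w in zip(per_dataset, weights):
                if (el, alt) in fracs:
                    num += w * fracs[(el, alt)]
                    den += w
            row.append(num / den if den > 0 else float("nan"))
        rows[el] = row
    return pd.DataFrame(rows, index=alts).T.rename_axis("element")
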