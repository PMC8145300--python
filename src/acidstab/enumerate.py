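"""Exhaustive generation of molecules from an atom palette.

Every connected, neutral, closed-shell structure buildable from the palette
within a heavy-atom size range is emitted exactly once, with hydrogens
implicit (fill-to-valence, not counted toward size) and rings restricted to
a minimum size.  Generation is two-staged:

1. all non-isomorphic connected simple skeleton graphs with bounded degree
   and girth >= ``min_ring_size`` (trees first, then edge augmentation);
2. for each skeleton, all (element, bond order) labelings satisfying the
   valence constraints, deduplicated by keeping only the lexicographically
   minimal labeling within each orbit of the skeleton's automorphism group.

Two labelings describe the same molecule iff a skeleton automorphism maps
one onto the other, and non-isomorphic skeletons can never collide, so the
emitted canonical SMILES are pairwise distinct by construction.  Generated
structures are Kekule structures: no aromatic perception, charges, radicals,
or stereoisomer multiplication.

:func:`oracle_enumerate` is an independent brute-force path (all labeled
adjacency assignments, filtered, canonicalized with RDKit) for small specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterator, Sequence

import networkx as nx
from rdkit import Chem

from acidstab.chem_io import MoleculeRecord, mol_from_graph, record_from_mol

#: default valences used when a palette is given as element symbols only
DEFAULT_VALENCES = {"C": 4, "N": 3, "O": 2, "Si": 4, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1}


@dataclass(frozen=True)
class EnumerationSpec:
    """Palette and constraints for exhaustive structure generation."""

    palette: tuple[tuple[str, int], ...]
    size_min: int = 3
    size_max: int = 8
    min_ring_size: int = 5
    bond_orders: tuple[int, ...] = (1, 2, 3)
    dedup: bool = True

    def __post_init__(self) -> None:
        if not self.palette:
            raise ValueError("palette must be non-empty")
        if not 1 <= self.size_min <= self.size_max:
            raise ValueError(f"need 1 <= size_min <= size_max, got {self.size_min}..{self.size_max}")
        if self.min_ring_size < 3:
            raise ValueError(f"min_ring_size must be >= 3, got {self.min_ring_size}")
        if not self.bond_orders or not set(self.bond_orders) <= {1, 2, 3}:
            raise ValueError(f"bond_orders must be a non-empty subset of {{1,2,3}}")
        for el, val in self.palette:
            if val < 1:
                raise ValueError(f"element {el!r}: valence must be >= 1")

    @property
    def max_valence(self) -> int:
        return max(v for _, v in self.palette)


def make_spec(
    elements: Sequence[str],
    size_min: int = 3,
    size_max: int = 8,
    min_ring_size: int = 5,
    bond_orders: Sequence[int] = (1, 2, 3),
) -> EnumerationSpec:
    """Spec from element symbols using default valences."""
    palette = tuple((el, DEFAULT_VALENCES[el]) for el in elements)
    return EnumerationSpec(
        palette=palette,
        size_min=size_min,
        size_max=size_max,
        min_ring_size=min_ring_size,
        bond_orders=tuple(sorted(bond_orders)),
    )


def skeleton_graphs(n: int, max_degree: int, min_ring_size: int) -> list[nx.Graph]:
    """Non-isomorphic connected simple graphs: n nodes, bounded degree, girth >= min_ring_size.

    Trees are taken from networkx; cyclic skeletons are built by repeated
    edge augmentation with isomorphism rejection.  Adding edge (u, v) creates
    cycles only through (u, v), so the new girth is bounded by the prior
    shortest u-v path length plus one.
    """
    if n < 1:
        return []
    if n == 1:
        return [nx.empty_graph(1)]
    if n == 2:
        return [nx.path_graph(2)] if max_degree >= 1 else []
    level = [
        t for t in nx.nonisomorphic_trees(n)
        if max(dict(t.degree).values()) <= max_degree
    ]
    out = list(level)
    while level:
        nxt: list[nx.Graph] = []
        for g in level:
            for u, v in combinations(g.nodes, 2):
                if g.has_edge(u, v):
                    continue
                if g.degree(u) >= max_degree or g.degree(v) >= max_degree:
                    continue
                if nx.shortest_path_length(g, u, v) < min_ring_size - 1:
                    continue
                h = g.copy()
                h.add_edge(u, v)
                if not any(nx.is_isomorphic(h, k) for k in nxt):
                    nxt.append(h)
        out.extend(nxt)
        level = nxt
    return out


def _edge_list(g: nx.Graph) -> list[tuple[int, int]]:
    return sorted(tuple(sorted(e)) for e in g.edges)


def _automorphism_perms(
    g: nx.Graph, edges: list[tuple[int, int]]
) -> list[tuple[list[int], list[int]]]:
    """Non-identity automorphisms as (inverse node perm, inverse edge perm)."""
    n = g.number_of_nodes()
    m = len(edges)
    eidx = {e: i for i, e in enumerate(edges)}
    perms = []
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, g)
    for mapping in matcher.isomorphisms_iter():
        nperm = tuple(mapping[i] for i in range(n))
        eperm = tuple(eidx[tuple(sorted((mapping[u], mapping[v])))] for u, v in edges)
        if nperm == tuple(range(n)) and eperm == tuple(range(m)):
            continue
        inv_n = [0] * n
        for i, p in enumerate(nperm):
            inv_n[p] = i
        inv_e = [0] * m
        for i, p in enumerate(eperm):
            inv_e[p] = i
        perms.append((inv_n, inv_e))
    return perms


def _labelings(
    g: nx.Graph, spec: EnumerationSpec
) -> Iterator[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Canonical (element index per node, bond order per edge) labelings of one skeleton.

    Yields exactly one representative per automorphism orbit.
    """
    n = g.number_of_nodes()
    edges = _edge_list(g)
    m = len(edges)
    aut = _automorphism_perms(g, edges)
    deg = [g.degree(i) for i in range(n)]
    incident: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for i, (u, v) in enumerate(edges):
        incident[u].append((i, v))
        incident[v].append((i, u))
    orders = tuple(sorted(spec.bond_orders))
    palette = spec.palette

    elem = [0] * n
    valof = [0] * n
    eord = [0] * m
    used = [0] * n

    def is_minimal() -> bool:
        key = (tuple(elem), tuple(eord))
        for inv_n, inv_e in aut:
            image = (
                tuple(elem[inv_n[i]] for i in range(n)),
                tuple(eord[inv_e[i]] for i in range(m)),
            )
            if image < key:
                return False
        return True

    def assign_node(v: int) -> Iterator[tuple[tuple[int, ...], tuple[int, ...]]]:
        if v == n:
            if not aut or is_minimal():
                yield tuple(elem), tuple(eord)
            return
        pend = [(ei, u) for ei, u in incident[v] if u < v]
        later_v = sum(1 for _, w in incident[v] if w > v)

        def assign_edges(k: int) -> Iterator[tuple[tuple[int, ...], tuple[int, ...]]]:
            if k == len(pend):
                yield from assign_node(v + 1)
                return
            ei, u = pend[k]
            rem_v = later_v + (len(pend) - k - 1)
            rem_u = sum(1 for _, w in incident[u] if w > v)
            for o in orders:
                if used[v] + o + rem_v > valof[v]:
                    break
                if used[u] + o + rem_u > valof[u]:
                    continue
                eord[ei] = o
                used[v] += o
                used[u] += o
                yield from assign_edges(k + 1)
                used[v] -= o
                used[u] -= o

        for pi, (_, valence) in enumerate(palette):
            if valence < deg[v]:
                continue
            elem[v] = pi
            valof[v] = valence
            yield from assign_edges(0)
        elem[v] = 0

    yield from assign_node(0)


def _iter_structures(
    spec: EnumerationSpec,
) -> Iterator[tuple[nx.Graph, tuple[int, ...], tuple[int, ...], list[tuple[int, int]]]]:
    for n in range(spec.size_min, spec.size_max + 1):
        for g in skeleton_graphs(n, spec.max_valence, spec.min_ring_size):
            edges = _edge_list(g)
            for elems, eords in _labelings(g, spec):
                yield g, elems, eords, edges


def enumerate_structures(spec: EnumerationSpec) -> Iterator[MoleculeRecord]:
    """Stream every structure satisfying the spec, one record per canonical form.

    Output order is deterministic: size ascending, then skeleton generation
    order, then labeling DFS order.
    """
    counter = 0
    for g, elems, eords, edges in _iter_structures(spec):
        elements = [spec.palette[e][0] for e in elems]
        bonds = [(u, v, o) for (u, v), o in zip(edges, eords)]
        mol = mol_from_graph(elements, bonds)
        counter += 1
        yield record_from_mol(mol, f"enum-{counter}", Chem.MolToSmiles(mol))


def count_structures(spec: EnumerationSpec) -> int:
    """Number of distinct structures, without materializing SMILES."""
    return sum(1 for _ in _iter_structures(spec))


# independent brute-force path ------------------------------------------------

_ORACLE_WORK_LIMIT = 50_000_000


def oracle_enumerate(spec: EnumerationSpec) -> set[str]:
    """Brute-force canonical-SMILES set for small specs (size_max <= 5).

    Iterates over every element labeling and every bond-order assignment of
    every atom pair (0 = no bond), filters for connectivity, valence and ring
    size, and canonicalizes with RDKit.  Refuses combinatorially infeasible
    inputs.
    """
    if spec.size_max > 5:
        raise ValueError("oracle_enumerate is limited to size_max <= 5")
    out: set[str] = set()
    orders = (0,) + tuple(sorted(spec.bond_orders))
    for n in range(spec.size_min, spec.size_max + 1):
        pairs = list(combinations(range(n), 2))
        work = len(spec.palette) ** n * len(orders) ** len(pairs)
        if work > _ORACLE_WORK_LIMIT:
            raise ValueError(f"oracle workload {work} exceeds limit for n={n}")
        for elems in product(range(len(spec.palette)), repeat=n):
            valences = [spec.palette[e][1] for e in elems]
            for assignment in product(orders, repeat=len(pairs)):
                used = [0] * n
                ok = True
                for (u, v), o in zip(pairs, assignment):
                    used[u] += o
                    used[v] += o
                for i in range(n):
                    if used[i] > valences[i] or (n > 1 and used[i] == 0):
                        ok = False
                        break
                if not ok:
                    continue
                g = nx.Graph()
                g.add_nodes_from(range(n))
                g.add_edges_from(uv for uv, o in zip(pairs, assignment) if o > 0)
                if not nx.is_connected(g):
                    continue
                if g.number_of_edges() >= n and nx.girth(g) < spec.min_ring_size:
                    continue
                try:
                    mol = mol_from_graph(
                        [spec.palette[e][0] for e in elems],
                        [(u, v, o) for (u, v), o in zip(pairs, assignment) if o > 0],
                    )
                except Exception:
                    continue
                out.add(Chem.MolToSmiles(mol))
    return out
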