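"""Molecular graphs, exact maximum common substructure, and ligand similarity.

The similarity measure used to call a ligand pair "very different" is

    ratio = |MCS(a, b)| / min(|a|, |b|)        (very different iff ratio < 0.5)

where |.| counts heavy atoms and the MCS is the largest **connected** common
subgraph under exact element match and exact bond-order match (aromatic
matches only aromatic).  The MCS search is an exact branch-and-bound over
shared-edge extensions; it is deterministic, and only its size is consumed so
tie-breaking among equally large substructures is irrelevant.  An
``engine`` hook lets callers substitute an external MCS implementation for
cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import networkx as nx
import numpy as np

from .errors import SizeLimitError, SmilesParseError

__all__ = [
    "AROMATIC",
    "MolGraph",
    "SimilarityResult",
    "parse_smiles",
    "to_smiles",
    "molgraph_from_rdkit",
    "mcs_size",
    "similarity_ratio",
    "automorphisms",
]

#: Sentinel bond order for aromatic bonds (matches only itself).
AROMATIC = 1.5

#: Heavy-atom cap for the exact MCS search.
MCS_ATOM_CAP = 80

_ORDER_NAMES = {1.0: "single", 2.0: "double", 3.0: "triple", AROMATIC: "aromatic"}


@dataclass(frozen=True)
class MolGraph:
    """A heavy-atom chemical graph: element-labeled atoms, order-labeled bonds.

    Simple and connected by construction; bond orders are 1, 2, 3 or
    :data:`AROMATIC`.
    """

    elements: tuple
    bonds: tuple  # of (i, j, order) with i < j

    def __post_init__(self) -> None:
        n = len(self.elements)
        seen = set()
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError("self-loop bond")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond index out of range")
            if order not in _ORDER_NAMES:
                raise ValueError(f"bond order must be one of {sorted(_ORDER_NAMES)}")
            e = (min(i, j), max(i, j))
            if e in seen:
                raise ValueError("duplicate bond")
            seen.add(e)
        if n > 1 and not nx.is_connected(self.to_networkx()):
            raise ValueError("molecular graph must be connected")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def adjacency(self) -> dict:
        adj: dict = {i: {} for i in range(self.n_atoms)}
        for i, j, order in self.bonds:
            adj[i][j] = order
            adj[j][i] = order
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g


def canonical_bonds(bonds) -> tuple:
    return tuple(sorted((min(i, j), max(i, j), float(order)) for i, j, order in bonds))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_RDKIT_ORDERS = {"SINGLE": 1.0, "DOUBLE": 2.0, "TRIPLE": 3.0, "AROMATIC": AROMATIC}


def molgraph_from_rdkit(mol, heavy_indices: Optional[list] = None) -> MolGraph:
    """Build a :class:`MolGraph` from an RDKit molecule (heavy atoms only)."""
    if heavy_indices is None:
        heavy_indices = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    index = {idx: k for k, idx in enumerate(heavy_indices)}
    elements = tuple(mol.GetAtomWithIdx(i).GetSymbol() for i in heavy_indices)
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in index and j in index:
            name = b.GetBondType().name
            order = _RDKIT_ORDERS.get(name)
            if order is None:
                raise SmilesParseError(f"unsupported bond type {name}")
            bonds.append((index[i], index[j], order))
    return MolGraph(elements=elements, bonds=canonical_bonds(bonds))


def parse_smiles(s: str) -> MolGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolGraph`.

    Aromaticity is taken as written (lowercase atoms / aromatic bond flags);
    Kekule-written rings are *not* re-perceived as aromatic.  Hydrogens are
    dropped; multi-fragment SMILES are rejected.
    """
    from rdkit import Chem

    if "." in s:
        raise SmilesParseError(f"multi-fragment SMILES rejected: {s!r}")
    mol = Chem.MolFromSmiles(s, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {s!r}")
    try:
        mol.UpdatePropertyCache(strict=False)
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        raise SmilesParseError(f"invalid SMILES: {s!r} ({exc})") from exc
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"empty SMILES: {s!r}")
    try:
        return molgraph_from_rdkit(mol)
    except ValueError as exc:
        raise SmilesParseError(f"{s!r}: {exc}") from exc


def to_smiles(graph: MolGraph) -> str:
    """Serialize a :class:`MolGraph` to SMILES (bond orders as stored)."""
    from rdkit import Chem

    order_types = {
        1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC,
    }
    mol = Chem.RWMol()
    for el in graph.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    aromatic_atoms = set()
    for i, j, order in graph.bonds:
        mol.AddBond(int(i), int(j), order_types[order])
        if order == AROMATIC:
            aromatic_atoms.update((i, j))
            mol.GetBondBetweenAtoms(int(i), int(j)).SetIsAromatic(True)
    for i in aromatic_atoms:
        mol.GetAtomWithIdx(int(i)).SetIsAromatic(True)
    mol.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Automorphisms (for symmetry-corrected pose RMSD)
# ---------------------------------------------------------------------------

def automorphisms(graph: MolGraph, cap: int = 10_000) -> list:
    """Enumerate graph automorphisms as index permutation arrays.

    Node match: element; edge match: bond order.  If more than ``cap``
    automorphisms exist, fall back to the identity with a warning.
    """
    import warnings

    g = graph.to_networkx()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    perms = []
    for iso in matcher.isomorphisms_iter():
        perms.append(np.array([iso[i] for i in range(graph.n_atoms)], dtype=int))
        if len(perms) > cap:
            warnings.warn(
                f"more than {cap} automorphisms; falling back to identity mapping",
                stacklevel=2,
            )
            return [np.arange(graph.n_atoms)]
    return perms or [np.arange(graph.n_atoms)]


# ---------------------------------------------------------------------------
# Maximum common substructure
# ---------------------------------------------------------------------------

def _element_bound(unmapped_a: set, unmapped_b: set, elements_a, elements_b) -> int:
    """Upper bound on further growth from element multiset intersection."""
    count_a: dict = {}
    for i in unmapped_a:
        count_a[elements_a[i]] = count_a.get(elements_a[i], 0) + 1
    count_b: dict = {}
    for j in unmapped_b:
        count_b[elements_b[j]] = count_b.get(elements_b[j], 0) + 1
    return sum(min(c, count_b.get(el, 0)) for el, c in count_a.items())


def mcs_size(a: MolGraph, b: MolGraph, engine: Optional[Callable] = None) -> int:
    """Size (heavy atoms) of the maximum common connected substructure.

    Exact branch-and-bound: a partial atom mapping is grown one pair at a
    time, each new pair attached to the mapped core through an edge present
    in *both* molecules with identical bond order, so the common substructure
    is connected by construction.  Pruned by an element-multiset bound and a
    visited-mapping table; deterministic.

    ``engine`` substitutes an external MCS implementation (called as
    ``engine(a, b) -> int``) for cross-checking.
    """
    if engine is not None:
        return int(engine(a, b))
    if a.n_atoms > MCS_ATOM_CAP or b.n_atoms > MCS_ATOM_CAP:
        raise SizeLimitError(
            f"molecule exceeds {MCS_ATOM_CAP} heavy atoms; "
            "pass an external MCS engine via the `engine` hook"
        )
    if a.n_atoms == 0 or b.n_atoms == 0:
        return 0
    adj_a, adj_b = a.adjacency(), b.adjacency()
    els_a, els_b = a.elements, b.elements
    best = 0
    seen: set = set()

    def extend(mapping: dict, used_b: set) -> None:
        nonlocal best
        best = max(best, len(mapping))
        unmapped_a = set(range(a.n_atoms)) - mapping.keys()
        unmapped_b = set(range(b.n_atoms)) - used_b
        if len(mapping) + _element_bound(unmapped_a, unmapped_b, els_a, els_b) <= best:
            return
        candidates = []
        for ai, bi in mapping.items():
            for an, order in adj_a[ai].items():
                if an in mapping:
                    continue
                for bn, border in adj_b[bi].items():
                    if bn in used_b or border != order or els_a[an] != els_b[bn]:
                        continue
                    candidates.append((an, bn))
        for an, bn in sorted(set(candidates)):
            key = frozenset(mapping.items()) | {(an, bn)}
            if key in seen:
                continue
            seen.add(key)
            mapping[an] = bn
            extend(mapping, used_b | {bn})
            del mapping[an]

    order_a = sorted(range(a.n_atoms), key=lambda i: -len(adj_a[i]))
    for ai in order_a:
        for bi in range(b.n_atoms):
            if els_a[ai] == els_b[bi]:
                extend({ai: bi}, {bi})
                if best == min(a.n_atoms, b.n_atoms):
                    return best
    return best


@dataclass(frozen=True)
class SimilarityResult:
    """MCS-based similarity of a ligand pair."""

    mcs_size: int
    size_small: int
    ratio: float
    very_different: bool


def similarity_ratio(a: MolGraph, b: MolGraph, engine: Optional[Callable] = None,
                     threshold: float = 0.5) -> SimilarityResult:
    """MCS size over the size of the smaller molecule.

    A pair is flagged ``very_different`` when the ratio is strictly below
    ``threshold`` (default 0.5).
    """
    size = mcs_size(a, b, engine=engine)
    small = min(a.n_atoms, b.n_atoms)
    if small == 0:
        raise ValueError("similarity undefined for an empty molecule")
    ratio = size / small
    return SimilarityResult(
        mcs_size=size, size_small=small, ratio=ratio,
        very_different=bool(ratio < threshold),
    )
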