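"""Hydrogen-suppressed molecular graphs and structure parsing.

The graph container is the substrate for every topological descriptor:
heavy atoms with implicit hydrogen counts and formal charges, bonds with
order 1/2/3 or aromatic.  Structure input (MOL/SDF V2000 blocks and SMILES)
is parsed with RDKit and converted; explicit hydrogens are folded into the
implicit counts of their heavy neighbours.

Multi-fragment records (salts) are rejected by default; pass
``keep_largest=True`` to retain the largest fragment instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ._elements import SUPPORTED_ELEMENTS

AROMATIC = "aromatic"

try:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")  # parse errors are reported as exceptions
except ImportError as _exc:  # pragma: no cover
    Chem = None
    _rdkit_error = _exc


class MoleculeError(ValueError):
    """Base class for structure errors."""


class ParseError(MoleculeError):
    """Malformed MOL/SDF record or SMILES string."""


class UnsupportedElementError(MoleculeError):
    """Element outside the supported organic set."""


class DisconnectedStructureError(MoleculeError):
    """Multi-fragment record where a single molecule is required."""


@dataclass(frozen=True)
class Atom:
    """Heavy atom: element symbol, implicit H count, formal charge."""

    symbol: str
    n_h: int = 0
    charge: int = 0

    def __post_init__(self) -> None:
        if self.symbol not in SUPPORTED_ELEMENTS or self.symbol == "H":
            raise UnsupportedElementError(f"unsupported element {self.symbol!r}")
        if self.n_h < 0:
            raise MoleculeError("implicit H count must be >= 0")


@dataclass(frozen=True)
class Bond:
    """Bond between heavy atoms i < j with order 1, 2, 3 or 'aromatic'."""

    i: int
    j: int
    order: object = 1

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise MoleculeError("self-loop bond")
        if self.order not in (1, 2, 3, AROMATIC):
            raise MoleculeError(f"bad bond order {self.order!r}")
        if self.i > self.j:  # canonical orientation
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed simple graph of one organic molecule."""

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    hydrogen_suppressed: bool = True
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n < 1:
            raise MoleculeError("graph must contain at least one heavy atom")
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise MoleculeError(f"bond ({b.i}, {b.j}) references missing atom")
            key = (b.i, b.j)
            if key in seen:
                raise MoleculeError(f"duplicate bond ({b.i}, {b.j})")
            seen.add(key)

    # -- views -------------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> list[int]:
        return self.adjacency_lists()[i]

    def adjacency_lists(self) -> list[list[int]]:
        if "adj" not in self._cache:
            adj: list[list[int]] = [[] for _ in self.atoms]
            for b in self.bonds:
                adj[b.i].append(b.j)
                adj[b.j].append(b.i)
            self._cache["adj"] = adj
        return self._cache["adj"]

    def degrees(self) -> np.ndarray:
        """Heavy-atom degree delta per atom."""
        deg = np.zeros(self.n_atoms, dtype=np.int64)
        for b in self.bonds:
            deg[b.i] += 1
            deg[b.j] += 1
        return deg

    def bond_orders(self, i: int) -> list[object]:
        return [b.order for b in self.bonds if i in (b.i, b.j)]

    def is_connected(self) -> bool:
        if self.n_atoms == 1:
            return True
        adj = self.adjacency_lists()
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_atoms

    def require_connected(self) -> None:
        if not self.is_connected():
            raise DisconnectedStructureError(
                "descriptor requires a connected (single-fragment) structure"
            )

    def distance_matrix(self) -> np.ndarray:
        """Topological (bond-count) distances via BFS from every atom."""
        if "dist" not in self._cache:
            self.require_connected()
            n = self.n_atoms
            adj = self.adjacency_lists()
            D = np.full((n, n), -1, dtype=np.int64)
            for src in range(n):
                D[src, src] = 0
                queue = [src]
                while queue:
                    nxt = []
                    for u in queue:
                        for v in adj[u]:
                            if D[src, v] < 0:
                                D[src, v] = D[src, u] + 1
                                nxt.append(v)
                    queue = nxt
            self._cache["dist"] = D
        return self._cache["dist"]

    def hybridizations(self) -> list[str]:
        """Per-atom 'sp3' / 'sp2' / 'sp' inferred from bond orders."""
        out = []
        for i in range(self.n_atoms):
            orders = self.bond_orders(i)
            if 3 in orders or orders.count(2) >= 2:
                out.append("sp")
            elif 2 in orders or AROMATIC in orders:
                out.append("sp2")
            else:
                out.append("sp3")
        return out

    def relabelled(self, perm: list[int]) -> "MolecularGraph":
        """Graph with atom i moved to position perm[i] (test utility)."""
        inv = [0] * len(perm)
        for i, p in enumerate(perm):
            inv[p] = i
        atoms = tuple(self.atoms[inv[k]] for k in range(self.n_atoms))
        bonds = tuple(Bond(perm[b.i], perm[b.j], b.order) for b in self.bonds)
        return MolecularGraph(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# RDKit conversion
# ---------------------------------------------------------------------------

_ORDER_MAP = {
    "SINGLE": 1,
    "DOUBLE": 2,
    "TRIPLE": 3,
    "AROMATIC": AROMATIC,
}


def _require_rdkit() -> None:
    if Chem is None:  # pragma: no cover
        raise ImportError(f"RDKit is required for structure parsing: {_rdkit_error}")


def from_rdkit(mol, keep_largest: bool = False) -> MolecularGraph:
    """Convert an RDKit Mol into a hydrogen-suppressed MolecularGraph."""
    _require_rdkit()
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        if not keep_largest:
            raise DisconnectedStructureError(
                f"record contains {len(frags)} fragments; "
                "pass keep_largest=True to keep the biggest one"
            )
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    mol = Chem.RemoveHs(mol)
    if mol.GetNumHeavyAtoms() == 0:
        raise ParseError("no heavy atoms in record")

    atoms = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        if sym not in SUPPORTED_ELEMENTS or sym == "H":
            raise UnsupportedElementError(f"unsupported element {sym!r}")
        atoms.append(Atom(symbol=sym, n_h=a.GetTotalNumHs(), charge=a.GetFormalCharge()))
    bonds = []
    for b in mol.GetBonds():
        order = _ORDER_MAP.get(str(b.GetBondType()))
        if order is None:
            raise ParseError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms=tuple(atoms), bonds=tuple(bonds))


def parse_molfile(text: str, keep_largest: bool = False) -> MolecularGraph:
    """Parse one MOL/SDF V2000 record into a MolecularGraph."""
    _require_rdkit()
    if not text.strip():
        raise ParseError("empty MOL record")
    mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    if mol is None:
        raise ParseError("malformed MOL/SDF V2000 record")
    return from_rdkit(mol, keep_largest=keep_largest)


def parse_smiles(s: str, keep_largest: bool = False) -> MolecularGraph:
    """Parse a SMILES string into a MolecularGraph."""
    _require_rdkit()
    if not s.strip():
        raise ParseError("empty SMILES")
    mol = Chem.MolFromSmiles(s, sanitize=True)
    if mol is None:
        raise ParseError(f"invalid SMILES {s!r}")
    return from_rdkit(mol, keep_largest=keep_largest)


def iter_sdf(text: str) -> Iterator[tuple[str, str]]:
    """Yield (record name, record text) for each molecule in an SDF string."""
    for chunk in text.split("$$$$"):
        if chunk.strip():
            record = chunk.lstrip("\n")
            name = record.splitlines()[0].strip()
            yield name, record


def iter_smiles_file(text: str) -> Iterator[tuple[str, str]]:
    """Yield (id, smiles) from a SMILES list: one per line, optional
    tab-separated id after the SMILES."""
    for k, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        name = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"mol{k}"
        yield name, smiles
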