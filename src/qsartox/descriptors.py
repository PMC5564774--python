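"""Topological molecular descriptors from hydrogen-suppressed graphs.

Implements the classical graph-theoretic block: molecular weight, Kier-Hall
simple and valence-corrected connectivity indices (chi) over path, cluster
and path-cluster subgraphs, kappa shape indices with and without the
covalent-radius alpha correction, shape flexibility Phi, Wiener, Randic and
Balaban indices, Kier-Hall electrotopological states (S), hydrogen-bond
donor/acceptor counts, and element/functional-group counts.

Conventions that the literature leaves open are fixed as follows and tested:
the valence delta is (Z_v - h) / (Z - Z_v - 1); H-bond donors count heavy
O/N atoms bearing at least one hydrogen (not the hydrogens themselves);
acceptors count O plus N excluding pyrrole-type and amide nitrogens.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable

import numpy as np
import pandas as pd

from ._elements import (
    ATOMIC_MASS,
    ATOMIC_NUMBER,
    PRINCIPAL_QUANTUM,
    VALENCE_ELECTRONS,
    kier_alpha,
)
from .graph import AROMATIC, MolecularGraph, MoleculeError

logger = logging.getLogger(__name__)

CHI_KINDS = ("path", "cluster", "path-cluster")


class UndefinedIndexError(MoleculeError):
    """Index is undefined for this graph (too few atoms or no subgraphs)."""


# ---------------------------------------------------------------------------
# simple descriptors
# ---------------------------------------------------------------------------


def molecular_weight(g: MolecularGraph) -> float:
    """Sum of standard atomic masses including implicit hydrogens, g/mol."""
    mass = 0.0
    for atom in g.atoms:
        mass += ATOMIC_MASS[atom.symbol] + atom.n_h * ATOMIC_MASS["H"]
    return mass


def wiener_index(g: MolecularGraph) -> int:
    """Half-sum of the topological distance matrix."""
    D = g.distance_matrix()
    return int(np.sum(D) // 2)


def randic_index(g: MolecularGraph) -> float:
    """First-order connectivity index: sum over edges of (d_i d_j)^-1/2."""
    g.require_connected()
    if g.n_bonds == 0:
        raise UndefinedIndexError("Randic index needs at least one bond")
    deg = g.degrees()
    return float(sum(1.0 / np.sqrt(deg[b.i] * deg[b.j]) for b in g.bonds))


def balaban_index(g: MolecularGraph) -> float:
    """Balaban distance-connectivity index J."""
    g.require_connected()
    M = g.n_bonds
    if M == 0:
        return 0.0
    D = g.distance_matrix()
    s = D.sum(axis=1).astype(float)
    gamma = M - g.n_atoms + 1  # cyclomatic number of a connected graph
    total = sum(1.0 / np.sqrt(s[b.i] * s[b.j]) for b in g.bonds)
    return float(M / (gamma + 1.0) * total)


# ---------------------------------------------------------------------------
# connectivity (chi) indices
# ---------------------------------------------------------------------------


def valence_deltas(g: MolecularGraph) -> np.ndarray:
    """Kier-Hall valence delta (Z_v - h) / (Z - Z_v - 1) per heavy atom."""
    out = np.empty(g.n_atoms)
    for k, atom in enumerate(g.atoms):
        zv = VALENCE_ELECTRONS[atom.symbol]
        z = ATOMIC_NUMBER[atom.symbol]
        denom = z - zv - 1
        num = zv - atom.n_h
        out[k] = num / denom if denom > 0 else float(num)
    return out


def _edge_subsets(g: MolecularGraph, m: int):
    """All connected m-edge subgraphs as (vertex tuple, edge index tuple).

    Combination enumeration with a union-find connectivity check; fine for
    the m <= 4 orders used here.
    """
    edges = [(b.i, b.j) for b in g.bonds]
    for combo in itertools.combinations(range(len(edges)), m):
        verts: dict[int, int] = {}
        parent: list[int] = []

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in combo:
            for v in edges[e]:
                if v not in verts:
                    verts[v] = len(parent)
                    parent.append(len(parent))
            ra, rb = find(verts[edges[e][0]]), find(verts[edges[e][1]])
            parent[ra] = rb
        roots = {find(i) for i in range(len(parent))}
        if len(roots) == 1:
            yield tuple(sorted(verts)), combo


def _classify_subgraph(g: MolecularGraph, verts, edge_idx) -> str | None:
    """Path / cluster / path-cluster kind of a connected edge subgraph."""
    m = len(edge_idx)
    if len(verts) != m + 1:
        return None  # contains a cycle: ring-type, not handled here
    deg = {v: 0 for v in verts}
    for e in edge_idx:
        b = g.bonds[e]
        deg[b.i] += 1
        deg[b.j] += 1
    dmax = max(deg.values())
    if dmax <= 2:
        return "path"
    if dmax == m:
        return "cluster"
    return "path-cluster"


def chi_index(
    g: MolecularGraph,
    order: int,
    kind: str = "path",
    valence: bool = False,
) -> float:
    """Kier-Hall connectivity index of the given order and subgraph kind.

    Sums prod(delta_v)^(-1/2) over all connected subgraphs with ``order``
    edges of the requested kind; an absent subgraph kind gives 0.
    """
    if kind not in CHI_KINDS:
        raise ValueError(f"kind must be one of {CHI_KINDS}")
    if not 0 <= order <= 4:
        raise ValueError("order must lie in 0..4")
    g.require_connected()
    deltas = valence_deltas(g) if valence else g.degrees().astype(float)
    if np.any(deltas <= 0):
        # an isolated atom (methane-like single vertex) has delta 0; the
        # order-0 term for it is conventionally skipped
        deltas = np.where(deltas <= 0, np.inf, deltas)
    if order == 0:
        if kind != "path":
            return 0.0
        return float(np.sum(1.0 / np.sqrt(deltas)))
    total = 0.0
    for verts, edge_idx in _edge_subsets(g, order):
        if _classify_subgraph(g, verts, edge_idx) == kind:
            total += 1.0 / np.sqrt(np.prod([deltas[v] for v in verts]))
    return float(total)


def path_count(g: MolecularGraph, length: int) -> int:
    """Number of path subgraphs with ``length`` edges (P_m in kappa)."""
    if length == 1:
        return g.n_bonds
    return sum(
        1
        for verts, eidx in _edge_subsets(g, length)
        if _classify_subgraph(g, verts, eidx) == "path"
    )


# ---------------------------------------------------------------------------
# kappa shape indices
# ---------------------------------------------------------------------------


def total_alpha(g: MolecularGraph) -> float:
    """Sum of Kier alpha contributions (covalent-radius ratios - 1)."""
    return float(
        sum(kier_alpha(a.symbol, h) for a, h in zip(g.atoms, g.hybridizations()))
    )


def kappa_indices(g: MolecularGraph, alpha_corrected: bool = False):
    """Kier shape indices (k1, k2, k3), optionally alpha-corrected.

    k1 = A(A-1)^2 / P1^2, k2 = (A-1)(A-2)^2 / P2^2, and k3 uses the even/odd
    A convention: (A-1)(A-3)^2 / P3^2 for even A, (A-3)(A-2)^2 / P3^2 for
    odd A.  The alpha correction adds the covalent-radius sum to both A and
    P_i terms.
    """
    g.require_connected()
    A = g.n_atoms
    if A < 3:
        raise UndefinedIndexError("kappa indices need at least 3 heavy atoms")
    a = total_alpha(g) if alpha_corrected else 0.0
    P1 = path_count(g, 1)
    P2 = path_count(g, 2)
    P3 = path_count(g, 3)
    if P1 == 0 or P2 == 0:
        raise UndefinedIndexError("kappa needs at least one 1- and 2-edge path")
    k1 = (A + a) * (A + a - 1.0) ** 2 / (P1 + a) ** 2
    k2 = (A + a - 1.0) * (A + a - 2.0) ** 2 / (P2 + a) ** 2
    if P3 == 0:
        k3 = float("nan")
    elif A % 2 == 0:
        k3 = (A + a - 1.0) * (A + a - 3.0) ** 2 / (P3 + a) ** 2
    else:
        k3 = (A + a - 3.0) * (A + a - 2.0) ** 2 / (P3 + a) ** 2
    return float(k1), float(k2), float(k3)


def flexibility_phi(g: MolecularGraph) -> float:
    """Kier shape flexibility Phi = kappa1_alpha * kappa2_alpha / A."""
    k1a, k2a, _ = kappa_indices(g, alpha_corrected=True)
    return float(k1a * k2a / g.n_atoms)


# ---------------------------------------------------------------------------
# electrotopological state
# ---------------------------------------------------------------------------


def estate_indices(g: MolecularGraph) -> tuple[np.ndarray, float]:
    """Per-atom Kier-Hall E-state values and their molecular sum.

    Intrinsic state I = ((2/L)^2 delta_v + 1) / delta; the field perturbation
    (I_i - I_j) / (d_ij + 1)^2 sums antisymmetrically, so the molecular sum
    equals the sum of intrinsic states.
    """
    g.require_connected()
    deg = g.degrees().astype(float)
    if np.any(deg == 0):
        deg = np.where(deg == 0, 1.0, deg)  # single-atom convention
    dv = valence_deltas(g)
    L = np.array([PRINCIPAL_QUANTUM[a.symbol] for a in g.atoms], dtype=float)
    I = ((2.0 / L) ** 2 * dv + 1.0) / deg
    D = g.distance_matrix().astype(float)
    pert = (I[:, None] - I[None, :]) / (D + 1.0) ** 2
    np.fill_diagonal(pert, 0.0)
    S = I + pert.sum(axis=1)
    return S, float(S.sum())


# ---------------------------------------------------------------------------
# atom, group and H-bond counts
# ---------------------------------------------------------------------------


def _has_double_bonded(g: MolecularGraph, i: int, symbol: str) -> bool:
    for b in g.bonds:
        if b.order == 2 and i in (b.i, b.j):
            other = b.j if b.i == i else b.i
            if g.atoms[other].symbol == symbol:
                return True
    return False


def _is_carbonyl_carbon(g: MolecularGraph, i: int) -> bool:
    return g.atoms[i].symbol == "C" and _has_double_bonded(g, i, "O")


def _aromatic_atoms(g: MolecularGraph) -> set[int]:
    out = set()
    for b in g.bonds:
        if b.order == AROMATIC:
            out.add(b.i)
            out.add(b.j)
    return out


def atom_and_group_counts(g: MolecularGraph) -> dict[str, int]:
    """Element counts, halogen/heteroatom totals and functional groups.

    Matching rules (conventions, stated not inherited): hydroxyl = terminal
    O-H not in a carboxyl; amino = NH2 on carbon; aldehyde = CH=O; nitro =
    N bonded to two terminal oxygens with at least one double bond; cyano =
    C#N with terminal N; acid anhydride = C(=O)-O-C(=O); methyl = terminal
    CH3 on any heavy atom.
    """
    adj = g.adjacency_lists()
    deg = g.degrees()
    counts = {f"N{el}": 0 for el in ("O", "N", "F", "Cl", "Br", "I")}
    for atom in g.atoms:
        key = f"N{atom.symbol}"
        if key in counts:
            counts[key] += 1
    counts["NHal"] = counts["NF"] + counts["NCl"] + counts["NBr"] + counts["NI"]
    counts["NHet"] = sum(1 for a in g.atoms if a.symbol != "C")

    hydroxyl = amino = aldehyde = nitro = cyano = anhydride = methyl = 0
    for i, atom in enumerate(g.atoms):
        sym = atom.symbol
        if sym == "O" and atom.n_h >= 1 and deg[i] == 1:
            # exclude carboxyl O-H: the attached carbon also carries =O
            c = adj[i][0]
            if not _is_carbonyl_carbon(g, c):
                hydroxyl += 1
        if sym == "N" and atom.n_h == 2 and deg[i] == 1:
            if g.atoms[adj[i][0]].symbol == "C":
                amino += 1
        if sym == "C" and atom.n_h >= 1 and _has_double_bonded(g, i, "O"):
            aldehyde += 1
        if sym == "N":
            term_O = [
                j for j in adj[i] if g.atoms[j].symbol == "O" and deg[j] == 1
            ]
            if len(term_O) >= 2 and _has_double_bonded(g, i, "O"):
                nitro += 1
        if sym == "C":
            for b in g.bonds:
                if b.order == 3 and i in (b.i, b.j):
                    other = b.j if b.i == i else b.i
                    if g.atoms[other].symbol == "N" and deg[other] == 1:
                        cyano += 1
        if sym == "O" and deg[i] == 2 and atom.n_h == 0:
            if all(_is_carbonyl_carbon(g, j) for j in adj[i]):
                anhydride += 1
        if sym == "C" and atom.n_h == 3 and deg[i] == 1:
            methyl += 1

    counts.update(
        NOH=hydroxyl,
        NNH2=amino,
        NCHO=aldehyde,
        NNO2=nitro,
        NCN=cyano,
        Nanh=anhydride,
        NCH3=methyl,
    )
    return counts


def hbond_counts(g: MolecularGraph) -> tuple[int, int]:
    """(N_Hdon, N_Hacc) under the heavy-atom donor convention.

    Donors: O or N atoms carrying at least one hydrogen (counted once per
    heavy atom).  Acceptors: O plus N atoms, excluding pyrrole-type
    nitrogens (aromatic N bearing H or with three connections) and amide
    nitrogens (N adjacent to a carbonyl carbon).
    """
    aromatic = _aromatic_atoms(g)
    adj = g.adjacency_lists()
    deg = g.degrees()
    donors = acceptors = 0
    for i, atom in enumerate(g.atoms):
        if atom.symbol not in ("N", "O"):
            continue
        if atom.n_h >= 1:
            donors += 1
        if atom.symbol == "O":
            acceptors += 1
        else:
            pyrrole_type = i in aromatic and (atom.n_h >= 1 or deg[i] == 3)
            amide = any(_is_carbonyl_carbon(g, j) for j in adj[i])
            if not pyrrole_type and not amide:
                acceptors += 1
    return donors, acceptors


# ---------------------------------------------------------------------------
# descriptor block
# ---------------------------------------------------------------------------

#: fixed column order of the computed block
BLOCK_COLUMNS = (
    "MW",
    "chi0", "chi1", "chi2", "chi3p", "chi4p", "chi3c", "chi4pc",
    "chi0v", "chi1v", "chi2v", "chi3pv", "chi4pv", "chi3cv", "chi4pcv",
    "kappa1", "kappa2", "kappa3",
    "kappa1a", "kappa2a", "kappa3a",
    "phi", "W", "J", "S_sum",
    "NHdon", "NHacc",
    "NO", "NN", "NF", "NCl", "NBr", "NI", "NHal", "NHet",
    "NOH", "NNH2", "NCHO", "NNO2", "NCN", "Nanh", "NCH3",
)


def _descriptor_row(g: MolecularGraph) -> dict[str, float]:
    g.require_connected()
    row: dict[str, float] = {"MW": molecular_weight(g)}
    for valence, tag in ((False, ""), (True, "v")):
        row[f"chi0{tag}"] = chi_index(g, 0, "path", valence)
        row[f"chi1{tag}"] = chi_index(g, 1, "path", valence) if g.n_bonds else 0.0
        row[f"chi2{tag}"] = chi_index(g, 2, "path", valence)
        row[f"chi3p{tag}"] = chi_index(g, 3, "path", valence)
        row[f"chi4p{tag}"] = chi_index(g, 4, "path", valence)
        row[f"chi3c{tag}"] = chi_index(g, 3, "cluster", valence)
        row[f"chi4pc{tag}"] = chi_index(g, 4, "path-cluster", valence)
    for corrected, tag in ((False, ""), (True, "a")):
        try:
            k1, k2, k3 = kappa_indices(g, alpha_corrected=corrected)
        except UndefinedIndexError:
            k1 = k2 = k3 = 0.0
        row[f"kappa1{tag}"] = k1
        row[f"kappa2{tag}"] = k2
        row[f"kappa3{tag}"] = 0.0 if np.isnan(k3) else k3
    try:
        row["phi"] = flexibility_phi(g)
    except UndefinedIndexError:
        row["phi"] = 0.0
    row["W"] = float(wiener_index(g))
    row["J"] = balaban_index(g)
    row["S_sum"] = estate_indices(g)[1]
    don, acc = hbond_counts(g)
    row["NHdon"] = float(don)
    row["NHacc"] = float(acc)
    for key, val in atom_and_group_counts(g).items():
        row[key] = float(val)
    return row


def compute_descriptor_block(
    structures: Iterable[tuple[str, MolecularGraph]],
    on_error: str = "abort",
) -> pd.DataFrame:
    """Descriptor table for a batch of (compound id, graph) pairs.

    One row per compound, columns in the fixed :data:`BLOCK_COLUMNS` order.
    ``on_error='skip'`` drops failing structures with a logged warning;
    ``'abort'`` re-raises with the compound id attached.
    """
    if on_error not in ("abort", "skip"):
        raise ValueError("on_error must be 'abort' or 'skip'")
    ids: list[str] = []
    rows: list[dict[str, float]] = []
    for cid, g in structures:
        try:
            rows.append(_descriptor_row(g))
            ids.append(str(cid))
        except MoleculeError as exc:
            if on_error == "abort":
                raise type(exc)(f"compound {cid!r}: {exc}") from exc
            logger.warning("skipping compound %r: %s", cid, exc)
    if not rows:
        raise MoleculeError("empty batch: no structure yielded descriptors")
    df = pd.DataFrame(rows, columns=list(BLOCK_COLUMNS))
    df.insert(0, "compound_id", ids)
    return df
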