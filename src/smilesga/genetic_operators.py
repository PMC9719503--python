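"""Crossover and the named molecular mutations.

Operators act on parsed :class:`~smilesga.molgraph.MoleculeGraph` objects
and the chromosome text is regenerated by serialisation afterwards, so ring
renumbering is automatic.  Every operator is closed under validity: its
output parses, satisfies the valence model and stays a single connected
component; when no feasible edit exists the operator reports failure and
the dispatcher falls back to the identity (a GA run never crashes on an
impossible edit).

Crossover follows the segment semantics of the chromosome text: a segment
is the span from a chosen atom to the end of its enclosing branch (or of
the whole expression), which in the serialisation's DFS tree is exactly the
subtree rooted at that atom.  An atom on a ring is "ring-blocked" — a ring
cannot be split into two pieces by cutting one bond — and triggers a retry.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .molgraph import (
    ChromosomeError,
    DEFAULT_MOLECULAR_CONFIG,
    MolecularConfig,
    MoleculeGraph,
    traverse,
)

__all__ = [
    "MutationKind",
    "OperatorConfig",
    "SegmentSpan",
    "OperatorFailure",
    "classify_segment",
    "crossover",
    "crossover_at",
    "mutate",
    "apply_mutation",
    "DEFAULT_INTER_BOND_DISTANCE",
]


class MutationKind(str, enum.Enum):
    """The 14 molecular mutations (OPEN_BOND is deliberately absent)."""

    CHANGE_ATOM = "CHANGE_ATOM"
    ADD_ATOM = "ADD_ATOM"
    DELETE_ATOM = "DELETE_ATOM"
    ADD_BRANCH = "ADD_BRANCH"
    DELETE_BRANCH = "DELETE_BRANCH"
    CLOSE_RING = "CLOSE_RING"
    OPEN_RING = "OPEN_RING"
    INTERCHANGE_DIHEDRAL = "INTERCHANGE_DIHEDRAL"
    SINGLE_DOUBLE_BOND = "SINGLE_DOUBLE_BOND"
    DOUBLE_SINGLE_BOND = "DOUBLE_SINGLE_BOND"
    SINGLE_TRIPLE_BOND = "SINGLE_TRIPLE_BOND"
    TRIPLE_SINGLE_BOND = "TRIPLE_SINGLE_BOND"
    DOUBLE_TRIPLE_BOND = "DOUBLE_TRIPLE_BOND"
    TRIPLE_DOUBLE_BOND = "TRIPLE_DOUBLE_BOND"


# Single-bond equilibrium lengths (Å) per element pair; honoured by the
# optional geometric post-filter when a 3D-capable scorer supplies
# coordinates.  The purely topological core never reads them.
DEFAULT_INTER_BOND_DISTANCE: dict[frozenset, float] = {
    frozenset(p): d
    for p, d in {
        ("C", "C"): 1.53, ("C", "N"): 1.49, ("C", "O"): 1.43, ("C", "P"): 1.82,
        ("C", "S"): 1.81, ("C", "F"): 1.40, ("N", "N"): 1.45, ("N", "O"): 1.46,
        ("N", "P"): 1.68, ("N", "S"): 1.77, ("N", "F"): 1.30, ("O", "O"): 1.49,
        ("O", "P"): 1.61, ("O", "S"): 1.52, ("O", "F"): 1.21, ("P", "P"): 2.18,
        ("P", "S"): 2.12, ("P", "F"): 1.67, ("S", "S"): 2.05, ("S", "F"): 1.61,
    }.items()
}


class OperatorFailure(Exception):
    """Raised internally when an operator finds no feasible site."""


@dataclass
class OperatorConfig:
    """Tunable knobs of the molecular operators.

    ``unnorm_mut_probability`` holds one nonnegative weight per mutation
    kind under named keys (normalised at use); ``unnorm_percent_atom`` the
    per-element draw weights for atom creation/substitution.
    """

    molecular: MolecularConfig = field(default_factory=MolecularConfig)
    unnorm_mut_probability: dict[MutationKind, float] = field(
        default_factory=lambda: {kind: 1.0 for kind in MutationKind}
    )
    unnorm_percent_atom: dict[str, float] = field(
        default_factory=lambda: {el: 1.0 for el in ("C", "N", "O", "P", "S", "F")}
    )
    max_tries: int = 20
    min_heavy_atoms: int = 10
    cutoff_bond_percentage: float = 1.10
    inter_bond_distance: dict[frozenset, float] = field(
        default_factory=lambda: dict(DEFAULT_INTER_BOND_DISTANCE)
    )
    min_ring_size: int = 3
    max_ring_size: int = 8

    def __post_init__(self) -> None:
        if self.max_tries < 1:
            raise ValueError("max_tries must be >= 1")
        if all(w <= 0 for w in self.unnorm_mut_probability.values()):
            raise ValueError("at least one mutation weight must be positive")
        for k, w in self.unnorm_mut_probability.items():
            if w < 0:
                raise ValueError(f"negative mutation weight for {k}")
        for el, w in self.unnorm_percent_atom.items():
            if w < 0:
                raise ValueError(f"negative atom weight for {el}")

    def bond_length_ok(self, el_a: str, el_b: str, distance: float) -> bool:
        """Geometric feasibility filter for a prospective single bond: the
        observed distance must not exceed the tabulated equilibrium length
        times ``cutoff_bond_percentage``.  Only meaningful when a 3D-capable
        scorer adapter supplies coordinates."""
        ref = self.inter_bond_distance.get(frozenset((el_a, el_b)))
        if ref is None:
            return True
        return distance <= ref * self.cutoff_bond_percentage


DEFAULT_OPERATOR_CONFIG = OperatorConfig()


@dataclass(frozen=True)
class SegmentSpan:
    """A crossover segment: anchor atom, its kind, and the atom set from the
    anchor to the end of its enclosing branch/expression."""

    anchor: int
    kind: str  # "branch" | "tail" | "ring-blocked"
    atoms: frozenset[int]


def classify_segment(graph: MoleculeGraph, atom: int) -> SegmentSpan:
    """Classify the segment starting at ``atom`` in the chromosome's own
    (deterministic) traversal.

    Ring atoms are ring-blocked; atoms on the unparenthesised main chain
    give tail segments (to the end of the expression); all others give
    branch segments (to the end of the enclosing branch).
    """
    if not 0 <= atom < graph.n_atoms:
        raise IndexError(f"atom index {atom} out of range")
    if atom in graph.ring_atom_set():
        return SegmentSpan(atom, "ring-blocked", frozenset())
    trav = traverse(graph)
    span = frozenset(trav.subtree(atom))
    kind = "tail" if atom in trav.main_chain() else "branch"
    return SegmentSpan(atom, kind, span)


# ---------------------------------------------------------------------------
# Graph surgery helpers
# ---------------------------------------------------------------------------


def _rebuild(
    graph: MoleculeGraph,
    keep: list[int],
    extra_elements: list[str] = (),
    extra_bonds: list[tuple[int, int, int]] = (),
) -> MoleculeGraph:
    """New validated graph from a subset of atoms plus grafted material.

    ``keep`` lists retained original indices (new index = position);
    ``extra_bonds`` use the new index space (>= len(keep) refers to
    ``extra_elements``).
    """
    pos = {old: k for k, old in enumerate(keep)}
    elements = [graph.elements[a] for a in keep] + list(extra_elements)
    bonds: list[tuple[int, int, int]] = []
    for i in keep:
        for j, order in graph.adj[i].items():
            if j in pos and i < j:
                bonds.append((pos[i], pos[j], order))
    bonds.extend(extra_bonds)
    return MoleculeGraph(elements, bonds, config=graph.config)


def _graft(
    host: MoleculeGraph,
    host_keep: list[int],
    attach_at: int,
    donor: MoleculeGraph,
    donor_atoms: list[int],
    donor_root: int,
    order: int,
) -> MoleculeGraph:
    """Replace the removed part of ``host`` with a donor subtree, bonding
    the donor root to ``attach_at`` with the given order."""
    host_pos = {old: k for k, old in enumerate(host_keep)}
    donor_pos = {old: len(host_keep) + k for k, old in enumerate(donor_atoms)}
    elements = [host.elements[a] for a in host_keep] + [
        donor.elements[a] for a in donor_atoms
    ]
    bonds: list[tuple[int, int, int]] = []
    for i in host_keep:
        for j, o in host.adj[i].items():
            if j in host_pos and i < j:
                bonds.append((host_pos[i], host_pos[j], o))
    dset = set(donor_atoms)
    for i in donor_atoms:
        for j, o in donor.adj[i].items():
            if j in dset and i < j:
                bonds.append((donor_pos[i], donor_pos[j], o))
    bonds.append((host_pos[attach_at], donor_pos[donor_root], order))
    return MoleculeGraph(elements, bonds, config=host.config)


# ---------------------------------------------------------------------------
# Crossover
# ---------------------------------------------------------------------------


def crossover_at(
    parent_a: MoleculeGraph,
    atom_a: int,
    parent_b: MoleculeGraph,
    atom_b: int,
) -> tuple[MoleculeGraph, MoleculeGraph]:
    """Deterministic segment exchange at explicit cut atoms.

    The right-segment of each parent (subtree from the cut atom) is grafted
    onto the other parent's cut site, reattached with the *receiving*
    parent's original bond order (string-splice semantics).  Raises
    :class:`OperatorFailure` if either atom is ring-blocked or a traversal
    root, and :class:`ChromosomeError` if a child fails validation.
    """
    trav_a = traverse(parent_a)
    trav_b = traverse(parent_b)
    for graph, atom, trav in ((parent_a, atom_a, trav_a), (parent_b, atom_b, trav_b)):
        if atom in graph.ring_atom_set():
            raise OperatorFailure(f"atom {atom} is ring-blocked")
        if trav.parent[atom] is None:
            raise OperatorFailure(f"atom {atom} is the traversal root")

    sub_a = sorted(trav_a.subtree(atom_a))
    sub_b = sorted(trav_b.subtree(atom_b))
    keep_a = [i for i in range(parent_a.n_atoms) if i not in set(sub_a)]
    keep_b = [i for i in range(parent_b.n_atoms) if i not in set(sub_b)]
    par_a = trav_a.parent[atom_a]
    par_b = trav_b.parent[atom_b]
    order_a = parent_a.adj[par_a][atom_a]
    order_b = parent_b.adj[par_b][atom_b]

    child_a = _graft(parent_a, keep_a, par_a, parent_b, sub_b, atom_b, order_a)
    child_b = _graft(parent_b, keep_b, par_b, parent_a, sub_a, atom_a, order_b)
    return child_a, child_b


def crossover(
    parent_a: MoleculeGraph,
    parent_b: MoleculeGraph,
    config: OperatorConfig,
    rng: np.random.Generator,
) -> tuple[MoleculeGraph, MoleculeGraph]:
    """Random segment-exchange crossover.

    Retries ring-blocked picks up to ``max_tries`` per parent; a child that
    fails validation or falls below ``min_heavy_atoms`` is replaced by a
    copy of its parent.  Never raises on chemistry: after ``max_tries``
    total failures the unmodified parent copies are returned.
    """

    def pick(graph: MoleculeGraph, trav) -> Optional[int]:
        blocked = graph.ring_atom_set()
        for _ in range(config.max_tries):
            atom = int(rng.integers(0, graph.n_atoms))
            if atom not in blocked and trav.parent[atom] is not None:
                return atom
        return None

    trav_a = traverse(parent_a)
    trav_b = traverse(parent_b)
    atom_a = pick(parent_a, trav_a)
    atom_b = pick(parent_b, trav_b)
    if atom_a is None or atom_b is None:
        return parent_a.copy(), parent_b.copy()

    try:
        child_a, child_b = crossover_at(parent_a, atom_a, parent_b, atom_b)
    except (ChromosomeError, OperatorFailure):
        return parent_a.copy(), parent_b.copy()

    if child_a.n_atoms < config.min_heavy_atoms:
        child_a = parent_a.copy()
    if child_b.n_atoms < config.min_heavy_atoms:
        child_b = parent_b.copy()
    return child_a, child_b


# ---------------------------------------------------------------------------
# Individual mutations
# ---------------------------------------------------------------------------


def _draw_element(
    config: OperatorConfig,
    rng: np.random.Generator,
    feasible: Callable[[str], bool],
) -> Optional[str]:
    cands = [
        el
        for el in config.molecular.atom_types
        if config.unnorm_percent_atom.get(el, 0.0) > 0 and feasible(el)
    ]
    if not cands:
        return None
    weights = np.array([config.unnorm_percent_atom[el] for el in cands], dtype=float)
    return str(rng.choice(cands, p=weights / weights.sum()))


def change_atom(
    graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
) -> MoleculeGraph:
    """Replace one atom's element with a valence-feasible draw."""
    creation_val = config.molecular.atom_valences
    sites = [
        i
        for i in range(graph.n_atoms)
        if any(
            el != graph.elements[i]
            and config.unnorm_percent_atom.get(el, 0.0) > 0
            and creation_val[el] >= graph.bond_order_sum(i)
            for el in config.molecular.atom_types
        )
    ]
    if not sites:
        raise OperatorFailure("no atom admits a feasible element change")
    site = int(rng.choice(sites))
    bondsum = graph.bond_order_sum(site)
    el = _draw_element(
        config,
        rng,
        lambda e: e != graph.elements[site] and creation_val[e] >= bondsum,
    )
    if el is None:
        raise OperatorFailure("no feasible element to draw")
    g = graph.copy()
    g.elements[site] = el
    g._implicit_h = None
    g.validate()
    return g


def add_atom(
    graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
) -> MoleculeGraph:
    """Insert a new atom: splice into a single bond, or attach terminally to
    an atom with free valence."""
    creation_val = config.molecular.atom_valences
    splice_ok = any(creation_val[el] >= 2 and config.unnorm_percent_atom.get(el, 0) > 0
                    for el in config.molecular.atom_types)
    sites: list[tuple[str, tuple]] = []
    if splice_ok:
        sites += [
            ("splice", (b.i, b.j)) for b in graph.bonds() if b.order == 1
        ]
    sites += [
        ("terminal", (i,)) for i in range(graph.n_atoms) if graph.free_valence(i) >= 1
    ]
    if not sites:
        raise OperatorFailure("no feasible insertion site")
    mode, where = sites[int(rng.integers(0, len(sites)))]
    if mode == "splice":
        el = _draw_element(config, rng, lambda e: creation_val[e] >= 2)
        if el is None:
            raise OperatorFailure("no divalent element available")
        i, j = where
        g = graph.copy()
        del g.adj[i][j]
        del g.adj[j][i]
        new = len(g.elements)
        g.elements.append(el)
        g.adj.append({})
        g.adj[i][new] = 1
        g.adj[new][i] = 1
        g.adj[j][new] = 1
        g.adj[new][j] = 1
    else:
        el = _draw_element(config, rng, lambda e: True)
        if el is None:
            raise OperatorFailure("no element available")
        (i,) = where
        g = graph.copy()
        new = len(g.elements)
        g.elements.append(el)
        g.adj.append({})
        g.adj[i][new] = 1
        g.adj[new][i] = 1
    g._implicit_h = None
    g.validate()
    return g


def delete_atom(
    graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
) -> MoleculeGraph:
    """Delete an atom of heavy-degree <= 2, reconnecting a degree-2 atom's
    neighbours with a single bond (this is how a large ring is shortened)."""
    sites = []
    for i in range(graph.n_atoms):
        deg = graph.heavy_degree(i)
        if deg == 1:
            sites.append(i)
        elif deg == 2:
            u, v = graph.adj[i]
            if v not in graph.adj[u]:  # avoid creating a duplicate bond
                sites.append(i)
    if not sites or graph.n_atoms <= 1:
        raise OperatorFailure("no deletable atom")
    site = int(rng.choice(sites))
    keep = [a for a in range(graph.n_atoms) if a != site]
    nbrs = list(graph.adj[site])
    extra = []
    if len(nbrs) == 2:
        pos = {old: k for k, old in enumerate(keep)}
        extra = [(pos[nbrs[0]], pos[nbrs[1]], 1)]
    return _rebuild(graph, keep, extra_bonds=extra)


def add_branch(
    graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
) -> MoleculeGraph:
    """Attach a single new atom as a branch on a mid-chain atom (longer
    branches arise over iterations)."""
    sites = [
        i
        for i in range(graph.n_atoms)
        if graph.free_valence(i) >= 1 and graph.heavy_degree(i) >= 2
    ]
    if not sites:
        raise OperatorFailure("no branch-capable atom")
    el = _draw_element(config, rng, lambda e: True)
    if el is None:
        raise OperatorFailure("no element available")
    site = int(rng.choice(sites))
    g = graph.copy()
    new = len(g.elements)
    g.elements.append(el)
    g.adj.append({})
    g.adj[site][new] = 1
    g.adj[new][site] = 1
    g._implicit_h = None
    g.validate()
    return g


def delete_branch(
    graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
) -> MoleculeGraph:
    """Excise a whole terminal branch: the component hanging off one
    non-ring bond whose anchor atom has heavy-degree >= 3."""
    ring_bonds = graph.ring_bond_set()
    candidates: list[tuple[int, int]] = []  # (anchor, branch root)
    for b in graph.bonds():
        if (b.i, b.j) in ring_bonds:
            continue
        if graph.heavy_degree(b.i) >= 3:
            candidates.append((b.i, b.j))
        if graph.heavy_degree(b.j) >= 3:
            candidates.append((b.j, b.i))
    if not candidates:
        raise OperatorFailure("no terminal branch to delete")
    anchor, root = candidates[int(rng.integers(0, len(candidates)))]
    # component of root once the anchor atom is blocked off; the anchor bond
    # is a bridge, so this is exactly the branch hanging off it
    seen = _component_without(graph, root, anchor)
    keep = [a for a in range(graph.n_atoms) if a not in seen]
    return _rebuild(graph, keep)


def close_ring(
    graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
) -> MoleculeGraph:
    """Add a single bond between two free-valence atoms at graph distance
    2..7, creating one new ring of 3-8 atoms."""
    import networkx as nx

    g_nx = graph.to_networkx()
    lengths = dict(nx.all_pairs_shortest_path_length(g_nx, cutoff=config.max_ring_size - 1))
    pairs = []
    for u in range(graph.n_atoms):
        if graph.free_valence(u) < 1:
            continue
        for v, d in lengths[u].items():
            if v <= u or graph.free_valence(v) < 1:
                continue
            if v in graph.adj[u]:
                continue
            if config.min_ring_size - 1 <= d <= config.max_ring_size - 1:
                pairs.append((u, v))
    if not pairs:
        raise OperatorFailure("no closable atom pair")
    u, v = pairs[int(rng.integers(0, len(pairs)))]
    g = graph.copy()
    g.adj[u][v] = 1
    g.adj[v][u] = 1
    g._implicit_h = None
    g.validate()
    return g


def open_ring(
    graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
) -> MoleculeGraph:
    """Remove one ring-closure bond of the chromosome's own traversal (the
    bonds written as digit pairs), keeping the graph connected."""
    trav = traverse(graph)
    if not trav.back_edges:
        raise OperatorFailure("no ring to open")
    a, b = trav.back_edges[int(rng.integers(0, len(trav.back_edges)))]
    g = graph.copy()
    del g.adj[a][b]
    del g.adj[b][a]
    g._implicit_h = None
    g.validate()
    return g


def interchange_dihedral(
    graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
) -> MoleculeGraph:
    """Exchange one substituent branch from each side of an acyclic bond.

    Pure graph rewiring: the atom and bond multisets are preserved, so the
    molecular formula is conserved.
    """
    ring_bonds = graph.ring_bond_set()

    def bridge(u: int, v: int) -> bool:
        return (min(u, v), max(u, v)) not in ring_bonds

    candidates = []
    for b in graph.bonds():
        if b.order != 1 or not bridge(b.i, b.j):
            continue
        us = [x for x in graph.adj[b.i] if x != b.j and bridge(b.i, x)]
        vs = [x for x in graph.adj[b.j] if x != b.i and bridge(b.j, x)]
        if us and vs:
            candidates.append((b.i, b.j, us, vs))
    if not candidates:
        raise OperatorFailure("no interchange-capable bond")
    u, v, us, vs = candidates[int(rng.integers(0, len(candidates)))]
    # substituent picks must lie on their own side of the (u, v) bridge
    side_u = _component_without(graph, u, v)
    us = [x for x in us if x in side_u]
    vs = [x for x in vs if x not in side_u]
    if not us or not vs:
        raise OperatorFailure("substituents straddle the bond")
    bu = us[int(rng.integers(0, len(us)))]
    bv = vs[int(rng.integers(0, len(vs)))]
    o_u, o_v = graph.adj[u][bu], graph.adj[v][bv]
    g = graph.copy()
    del g.adj[u][bu]
    del g.adj[bu][u]
    del g.adj[v][bv]
    del g.adj[bv][v]
    if bv in g.adj[u] or bu in g.adj[v]:
        raise OperatorFailure("interchange would duplicate a bond")
    g.adj[u][bv] = o_v
    g.adj[bv][u] = o_v
    g.adj[v][bu] = o_u
    g.adj[bu][v] = o_u
    g._implicit_h = None
    g.validate()
    return g


def _component_without(graph: MoleculeGraph, start: int, excluded: int) -> set[int]:
    """Atoms reachable from ``start`` without passing through ``excluded``."""
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in graph.adj[x]:
            if y != excluded and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def _make_bond_changer(from_order: int, to_order: int):
    def op(
        graph: MoleculeGraph, config: OperatorConfig, rng: np.random.Generator
    ) -> MoleculeGraph:
        delta = to_order - from_order
        sites = []
        for b in graph.bonds():
            if b.order != from_order:
                continue
            if delta > 0 and (
                graph.free_valence(b.i) < delta or graph.free_valence(b.j) < delta
            ):
                continue
            sites.append((b.i, b.j))
        if not sites:
            raise OperatorFailure(f"no eligible bond of order {from_order}")
        i, j = sites[int(rng.integers(0, len(sites)))]
        g = graph.copy()
        g.adj[i][j] = to_order
        g.adj[j][i] = to_order
        g._implicit_h = None
        g.validate()
        return g

    op.__name__ = f"bond_order_{from_order}_to_{to_order}"
    return op


change_bond_order = _make_bond_changer  # factory, exported for tests

_MUTATION_FUNCS: dict[MutationKind, Callable] = {
    MutationKind.CHANGE_ATOM: change_atom,
    MutationKind.ADD_ATOM: add_atom,
    MutationKind.DELETE_ATOM: delete_atom,
    MutationKind.ADD_BRANCH: add_branch,
    MutationKind.DELETE_BRANCH: delete_branch,
    MutationKind.CLOSE_RING: close_ring,
    MutationKind.OPEN_RING: open_ring,
    MutationKind.INTERCHANGE_DIHEDRAL: interchange_dihedral,
    MutationKind.SINGLE_DOUBLE_BOND: _make_bond_changer(1, 2),
    MutationKind.DOUBLE_SINGLE_BOND: _make_bond_changer(2, 1),
    MutationKind.SINGLE_TRIPLE_BOND: _make_bond_changer(1, 3),
    MutationKind.TRIPLE_SINGLE_BOND: _make_bond_changer(3, 1),
    MutationKind.DOUBLE_TRIPLE_BOND: _make_bond_changer(2, 3),
    MutationKind.TRIPLE_DOUBLE_BOND: _make_bond_changer(3, 2),
}


def apply_mutation(
    graph: MoleculeGraph,
    kind: MutationKind,
    config: OperatorConfig,
    rng: np.random.Generator,
) -> MoleculeGraph:
    """Apply one named mutation at a random feasible site.

    Raises :class:`OperatorFailure` when no feasible site exists; the
    result is guaranteed valid and, for shrinking operators, is rejected
    (as a failure) if it would fall below ``min_heavy_atoms`` while the
    input was not already below it.
    """
    out = _MUTATION_FUNCS[kind](graph, config, rng)
    if out.n_atoms < config.min_heavy_atoms <= graph.n_atoms:
        raise OperatorFailure("result below min_heavy_atoms")
    return out


def mutate(
    graph: MoleculeGraph,
    config: OperatorConfig,
    rng: np.random.Generator,
) -> MoleculeGraph:
    """Dispatcher: draw a mutation kind by normalised weight and apply it
    with up to ``max_tries`` site retries; on total failure the input is
    returned unchanged (identity, never an exception)."""
    kinds = [k for k in MutationKind if config.unnorm_mut_probability.get(k, 0.0) > 0]
    weights = np.array([config.unnorm_mut_probability[k] for k in kinds], dtype=float)
    kind = kinds[int(rng.choice(len(kinds), p=weights / weights.sum()))]
    for _ in range(config.max_tries):
        try:
            return apply_mutation(graph, kind, config, rng)
        except (OperatorFailure, ChromosomeError):
            continue
    return graph.copy()
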