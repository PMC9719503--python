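"""Molecular graphs carried as SMILES chromosomes.

A chromosome is a non-isomeric SMILES string over the neutral-organic
alphabet C, N, O, P, S, F written in Kekulé form (explicit single/double/
triple bonds, no aromatic lowercase tokens).  This module parses such
strings into hydrogen-implicit molecular graphs, validates them against a
fixed valence model, serialises them back (with ring-closure digits freshly
numbered in traversal order), and measures the structural descriptors the
rest of the package needs: ring census, stereo elements, and the ADME-
relevant property profile.

The valence model is deliberately small: C=4, N=3, O=2, P=3, S=2, F=1.
Sulfur is additionally *accepted* at valence 4 or 6 on input (sulfonamides
appear in real drug molecules), but mutation operators only ever create
sulfur at valence 2.  No formal charges, no isotopes, no aromatic
perception.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import networkx as nx

__all__ = [
    "ChromosomeError",
    "SmilesSyntaxError",
    "ValenceError",
    "MolecularConfig",
    "AtomNode",
    "BondEdge",
    "MoleculeGraph",
    "StereoAssignment",
    "RingCensus",
    "PropertyProfile",
    "ATOMIC_MASSES",
    "parse_smiles",
    "write_smiles",
    "canonical_key",
    "perceive_rings",
    "ring_bond_census",
    "find_stereo_elements",
    "enumerate_stereoisomers",
    "compute_properties",
]


class ChromosomeError(ValueError):
    """Base class for invalid-chromosome signals.

    Callers in the GA never crash on these: an individual raising one is
    assigned the failure fitness instead.
    """


class SmilesSyntaxError(ChromosomeError):
    """Malformed SMILES text (unbalanced parentheses, unmatched ring digit...)."""


class ValenceError(ChromosomeError):
    """An atom's bond-order sum exceeds every allowed valence for its element."""


# Default atomic masses (Daltons) for the chromosome alphabet plus hydrogen.
# Hydrogen is not part of the heavy-atom alphabet but is needed to complete
# implicit valences when summing molecular mass.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.065,
    "F": 18.998,
    "H": 1.008,
}


@dataclass(frozen=True)
class MolecularConfig:
    """Alphabet and valence model for chromosomes.

    ``atom_types`` / ``atom_valences`` define the creation valence used when
    operators build atoms; ``input_valences`` lists every valence tolerated
    when *parsing* (hypervalent sulfur only).
    """

    atom_types: tuple[str, ...] = ("C", "N", "O", "P", "S", "F")
    atom_valences: dict[str, int] = field(
        default_factory=lambda: {"C": 4, "N": 3, "O": 2, "P": 3, "S": 2, "F": 1}
    )
    input_valences: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "C": (4,),
            "N": (3,),
            "O": (2,),
            "P": (3,),
            "S": (2, 4, 6),
            "F": (1,),
        }
    )
    max_stereoisomers: int = 512

    def allowed_valences(self, element: str) -> tuple[int, ...]:
        return self.input_valences[element]


DEFAULT_MOLECULAR_CONFIG = MolecularConfig()


@dataclass(frozen=True)
class AtomNode:
    """Read-only view of one atom: element, position, implicit hydrogens."""

    element: str
    index: int
    implicit_h: int


@dataclass(frozen=True)
class BondEdge:
    """Bond between two atom indices with integer order 1-3."""

    i: int
    j: int
    order: int
    in_ring: bool = False


class MoleculeGraph:
    """Hydrogen-implicit molecular graph; the chromosome's semantic form.

    Atoms are indexed 0..n-1; bonds live in a symmetric adjacency map of
    neighbour -> integer order.  The graph is validated on construction:
    connected, every bond order 1-3, and every atom's bond-order sum fits an
    allowed valence (implicit hydrogens fill the remainder).
    """

    __slots__ = ("elements", "adj", "source_smiles", "config", "_implicit_h")

    def __init__(
        self,
        elements: Sequence[str],
        bonds: Sequence[tuple[int, int, int]],
        source_smiles: Optional[str] = None,
        config: MolecularConfig = DEFAULT_MOLECULAR_CONFIG,
        validate: bool = True,
    ):
        self.elements: list[str] = list(elements)
        self.adj: list[dict[int, int]] = [dict() for _ in self.elements]
        self.source_smiles = source_smiles
        self.config = config
        for i, j, order in bonds:
            self._add_bond(i, j, order)
        self._implicit_h: Optional[list[int]] = None
        if validate:
            self.validate()

    # -- construction helpers -------------------------------------------------

    def _add_bond(self, i: int, j: int, order: int) -> None:
        if i == j:
            raise SmilesSyntaxError(f"self-bond at atom {i}")
        if j in self.adj[i]:
            raise SmilesSyntaxError(f"duplicate bond between atoms {i} and {j}")
        if order not in (1, 2, 3):
            raise SmilesSyntaxError(f"unsupported bond order {order}")
        self.adj[i][j] = order
        self.adj[j][i] = order

    def validate(self) -> None:
        """Valence + connectivity check (the chromosome validity check)."""
        if not self.elements:
            raise SmilesSyntaxError("empty molecule")
        for el in self.elements:
            if el not in self.config.atom_types:
                raise SmilesSyntaxError(f"element {el!r} outside alphabet")
        self._implicit_h = []
        for i in range(len(self.elements)):
            bondsum = sum(self.adj[i].values())
            fit = [v for v in self.config.allowed_valences(self.elements[i]) if v >= bondsum]
            if not fit:
                self._implicit_h = None
                raise ValenceError(
                    f"atom {i} ({self.elements[i]}) has bond-order sum {bondsum} "
                    f"exceeding allowed valences {self.config.allowed_valences(self.elements[i])}"
                )
            self._implicit_h.append(min(fit) - bondsum)
        # Connectivity: chromosomes never encode mixtures.
        if len(self.elements) > 1:
            seen = {0}
            stack = [0]
            while stack:
                u = stack.pop()
                for v in self.adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if len(seen) != len(self.elements):
                raise SmilesSyntaxError("disconnected molecular graph")

    # -- basic accessors ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_bonds(self) -> int:
        return sum(len(nbrs) for nbrs in self.adj) // 2

    def atoms(self) -> Iterator[AtomNode]:
        hs = self.implicit_h()
        for i, el in enumerate(self.elements):
            yield AtomNode(el, i, hs[i])

    def bonds(self) -> Iterator[BondEdge]:
        ring = self.ring_bond_set()
        for i, nbrs in enumerate(self.adj):
            for j, order in nbrs.items():
                if i < j:
                    yield BondEdge(i, j, order, (i, j) in ring)

    def bond_order(self, i: int, j: int) -> int:
        return self.adj[i][j]

    def heavy_degree(self, i: int) -> int:
        return len(self.adj[i])

    def bond_order_sum(self, i: int) -> int:
        return sum(self.adj[i].values())

    def implicit_h(self) -> list[int]:
        if self._implicit_h is None:
            self.validate()
        assert self._implicit_h is not None
        return self._implicit_h

    def free_valence(self, i: int) -> int:
        """Spare valence usable by operators (= implicit hydrogens)."""
        return self.implicit_h()[i]

    def copy(self) -> "MoleculeGraph":
        g = MoleculeGraph.__new__(MoleculeGraph)
        g.elements = list(self.elements)
        g.adj = [dict(nbrs) for nbrs in self.adj]
        g.source_smiles = self.source_smiles
        g.config = self.config
        g._implicit_h = list(self._implicit_h) if self._implicit_h is not None else None
        return g

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el)
        for i, nbrs in enumerate(self.adj):
            for j, order in nbrs.items():
                if i < j:
                    g.add_edge(i, j, order=order)
        return g

    def ring_bond_set(self) -> set[tuple[int, int]]:
        """Bonds on at least one cycle (non-bridges), as (i, j) with i < j."""
        g = self.to_networkx()
        bridges = {tuple(sorted(e)) for e in nx.bridges(g)} if g.number_of_edges() else set()
        return {
            (i, j)
            for i, nbrs in enumerate(self.adj)
            for j in nbrs
            if i < j and (i, j) not in bridges
        }

    def ring_atom_set(self) -> set[int]:
        return {a for bond in self.ring_bond_set() for a in bond}

    def is_isomorphic(self, other: "MoleculeGraph") -> bool:
        """Element/bond-order labelled graph isomorphism (stereo ignored)."""
        return nx.is_isomorphic(
            self.to_networkx(),
            other.to_networkx(),
            node_match=lambda a, b: a["element"] == b["element"],
            edge_match=lambda a, b: a["order"] == b["order"],
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MoleculeGraph({write_smiles(self)!r})"


@dataclass(frozen=True)
class StereoAssignment:
    """One point of the ± stereo basis.

    ``tetra_parity`` maps tetrahedral-centre atom index to '+'/'-';
    ``db_config`` maps an acyclic stereogenic double bond (i, j) to
    'cis'/'trans'.  ``index`` is the 0-based position in the deterministic
    enumeration order, matching the "stereoisomer k of 2^n" labelling.
    """

    index: int
    tetra_parity: tuple[tuple[int, str], ...]
    db_config: tuple[tuple[tuple[int, int], str], ...]


@dataclass(frozen=True)
class RingCensus:
    """SSSR-style ring perception result."""

    n_rings: int
    rings: tuple[tuple[tuple[int, int], ...], ...]  # per ring: its bonds (i<j)
    ring_bonds: frozenset[tuple[int, int]]

    def ring_sizes(self) -> tuple[int, ...]:
        return tuple(len(r) for r in self.rings)


@dataclass(frozen=True)
class PropertyProfile:
    """Structural descriptors feeding ADME penalties and the surrogate site.

    ``log_kow`` is input-only: the octanol-water partition coefficient is
    never computed here, a user may supply one.  ``hba`` defaults to the
    classic Lipinski N+O count; an override may be supplied when a
    pharmacophore-style acceptor count is preferred.
    """

    heavy_atoms: int
    molecular_mass: float
    hbd: int
    hba: int
    rotatable_dihedrals: int
    n_rings: int
    n_ring_bonds: int
    n_tetra_centers: int
    n_stereo_dbs: int
    log_kow: Optional[float] = None

    def with_overrides(self, **kwargs) -> "PropertyProfile":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?(?P<element>[A-Z][a-z]?)(?P<stereo>@{1,2})?"
    r"(?P<hcount>H\d*)?(?P<charge>[+-]\d*)?\]"
)

_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, "/": 1, "\\": 1}


def parse_smiles(
    text: str, config: MolecularConfig = DEFAULT_MOLECULAR_CONFIG
) -> MoleculeGraph:
    """Parse a Kekulé-dialect SMILES string into a validated MoleculeGraph.

    Accepted dialect: uppercase alphabet atoms (C N O P S F), bracket atoms
    for stereo-marked input (e.g. ``[C@@H]``, recorded then dropped), bonds
    ``- = #`` and directional ``/ \\`` (treated as single), branches ``()``,
    ring closures ``1``-``9`` and ``%nn`` (digits reusable once closed).
    Raises :class:`SmilesSyntaxError` on malformed text and
    :class:`ValenceError` when an atom exceeds its allowed valence.
    """
    if not text or not text.strip():
        raise SmilesSyntaxError("empty SMILES string")
    text = text.strip()

    elements: list[str] = []
    bonds: list[tuple[int, int, int]] = []
    stack: list[int] = []  # open branch anchors
    prev: Optional[int] = None
    pending_order: Optional[int] = None
    open_rings: dict[int, tuple[int, Optional[int]]] = {}  # digit -> (atom, order)

    def new_atom(element: str) -> None:
        nonlocal prev, pending_order
        if element not in config.atom_types:
            raise SmilesSyntaxError(f"element {element!r} outside alphabet {config.atom_types}")
        idx = len(elements)
        elements.append(element)
        if prev is not None:
            bonds.append((prev, idx, pending_order if pending_order is not None else 1))
        elif pending_order is not None:
            raise SmilesSyntaxError("bond symbol with no preceding atom")
        pending_order = None
        prev = idx

    def close_ring(digit: int) -> None:
        nonlocal pending_order
        if prev is None:
            raise SmilesSyntaxError("ring-closure digit before any atom")
        if digit in open_rings:
            other, open_order = open_rings.pop(digit)
            order = 1
            if open_order is not None and pending_order is not None:
                if open_order != pending_order:
                    raise SmilesSyntaxError(f"conflicting bond orders at ring closure {digit}")
                order = open_order
            elif open_order is not None:
                order = open_order
            elif pending_order is not None:
                order = pending_order
            if other == prev:
                raise SmilesSyntaxError(f"ring closure {digit} to the same atom")
            bonds.append((other, prev, order))
        else:
            open_rings[digit] = (prev, pending_order)
        pending_order = None

    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in _BOND_ORDERS:
            if pending_order is not None:
                raise SmilesSyntaxError(f"two consecutive bond symbols at position {i}")
            pending_order = _BOND_ORDERS[ch]
            i += 1
        elif ch == "(":
            if prev is None:
                raise SmilesSyntaxError("branch opened before any atom")
            if pending_order is not None:
                raise SmilesSyntaxError("bond symbol immediately before '('")
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmilesSyntaxError("unbalanced ')' in SMILES")
            if pending_order is not None:
                raise SmilesSyntaxError("dangling bond symbol before ')'")
            prev = stack.pop()
            i += 1
        elif ch.isdigit():
            close_ring(int(ch))
            i += 1
        elif ch == "%":
            m = re.match(r"%(\d\d)", text[i:])
            if not m:
                raise SmilesSyntaxError(f"malformed %nn ring closure at position {i}")
            close_ring(int(m.group(1)))
            i += len(m.group(0))
        elif ch == "[":
            m = _BRACKET_RE.match(text, i)
            if not m:
                raise SmilesSyntaxError(f"malformed bracket atom at position {i}")
            if m.group("isotope"):
                raise SmilesSyntaxError("isotope labels are not part of the chromosome dialect")
            if m.group("charge"):
                raise SmilesSyntaxError("formal charges are not part of the chromosome dialect")
            # Stereo mark and explicit H count are recorded by the dialect but
            # dropped: chromosomes are non-isomeric and hydrogens implicit.
            new_atom(m.group("element"))
            i = m.end()
        elif ch.isalpha() and ch.isupper():
            new_atom(ch)
            i += 1
        elif ch == ".":
            raise SmilesSyntaxError("multi-component SMILES ('.') not allowed: chromosomes are connected")
        elif ch.isspace():
            i += 1
        else:
            raise SmilesSyntaxError(f"unexpected character {ch!r} at position {i}")

    if stack:
        raise SmilesSyntaxError("unbalanced '(' in SMILES")
    if open_rings:
        raise SmilesSyntaxError(f"unmatched ring closure digit(s) {sorted(open_rings)}")
    if pending_order is not None:
        raise SmilesSyntaxError("dangling bond symbol at end of SMILES")

    return MoleculeGraph(elements, bonds, source_smiles=text, config=config)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Traversal:
    """Deterministic DFS of a graph: the serialisation skeleton.

    ``order`` is the visit sequence; ``parent`` maps atom -> tree parent
    (root has None); ``children`` lists tree children in emission order;
    ``back_edges`` are the ring-closure bonds as (opening atom, closing atom)
    in digit-assignment order.
    """

    root: int
    order: tuple[int, ...]
    parent: dict[int, Optional[int]]
    children: dict[int, tuple[int, ...]]
    back_edges: tuple[tuple[int, int], ...]

    def subtree(self, atom: int) -> set[int]:
        out = {atom}
        stack = [atom]
        while stack:
            u = stack.pop()
            for c in self.children[u]:
                out.add(c)
                stack.append(c)
        return out

    def main_chain(self) -> list[int]:
        chain = [self.root]
        while self.children[chain[-1]]:
            chain.append(self.children[chain[-1]][-1])
        return chain


def traverse(graph: MoleculeGraph, root: int = 0) -> Traversal:
    """DFS with ascending-index neighbour order; shared by the writer and
    the segment machinery so both agree on the chromosome's structure."""
    n = graph.n_atoms
    visited = [False] * n
    parent: dict[int, Optional[int]] = {root: None}
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    order: list[int] = []
    back_edges: list[tuple[int, int]] = []
    seen_back: set[tuple[int, int]] = set()

    stack: list[tuple[int, Optional[int]]] = [(root, None)]
    while stack:
        u, par = stack.pop()
        if visited[u]:
            continue
        visited[u] = True
        order.append(u)
        if par is not None:
            children[par].append(u)
        parent[u] = par
        nbrs = sorted(graph.adj[u])
        for v in nbrs:
            if v == par:
                continue
            if visited[v]:
                key = (min(u, v), max(u, v))
                if key not in seen_back:
                    seen_back.add(key)
                    back_edges.append((v, u))  # v visited earlier: opener
            # push in reverse so that the smallest-index neighbour is
            # expanded first (LIFO stack)
        for v in reversed(nbrs):
            if v != par and not visited[v]:
                stack.append((v, u))

    # A node may have been pushed twice; children may hold duplicates of
    # atoms adopted by an earlier parent.  Clean: keep only true tree edges.
    children = {u: [c for c in cs if parent.get(c) == u] for u, cs in children.items()}

    visit_pos = {a: k for k, a in enumerate(order)}
    back_edges.sort(key=lambda e: (visit_pos[e[0]], visit_pos[e[1]]))
    return Traversal(
        root=root,
        order=tuple(order),
        parent=parent,
        children={u: tuple(cs) for u, cs in children.items()},
        back_edges=tuple(back_edges),
    )


_ORDER_SYMBOL = {1: "", 2: "=", 3: "#"}


def write_smiles(graph: MoleculeGraph, root: int = 0) -> str:
    """Serialise a MoleculeGraph to Kekulé SMILES.

    Ring-closure digits are freshly numbered 1, 2, ... in traversal order
    (``%nn`` beyond 9); no stereo marks are emitted (chromosomes are
    non-isomeric).  The output re-parses to an isomorphic graph.
    """
    trav = traverse(graph, root)
    digit_of: dict[tuple[int, int], str] = {}
    for k, (a, b) in enumerate(trav.back_edges):
        num = k + 1
        tok = str(num) if num < 10 else f"%{num:02d}"
        digit_of[(min(a, b), max(a, b))] = tok

    # ring tokens attached at each endpoint, in back-edge order
    ring_tokens: dict[int, list[str]] = {i: [] for i in range(graph.n_atoms)}
    for a, b in trav.back_edges:
        tok = digit_of[(min(a, b), max(a, b))]
        sym = _ORDER_SYMBOL[graph.adj[a][b]]
        ring_tokens[a].append(sym + tok)
        ring_tokens[b].append(sym + tok)

    out: list[str] = []

    def emit(u: int) -> None:
        out.append(graph.elements[u])
        for tok in ring_tokens[u]:
            out.append(tok)
        cs = trav.children[u]
        for k, c in enumerate(cs):
            bond_sym = _ORDER_SYMBOL[graph.adj[u][c]]
            if k < len(cs) - 1:
                out.append("(")
                out.append(bond_sym)
                emit(c)
                out.append(")")
            else:
                out.append(bond_sym)
                emit(c)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, graph.n_atoms * 4 + 100))
    try:
        emit(trav.root)
    finally:
        sys.setrecursionlimit(old)
    return "".join(out)


# ---------------------------------------------------------------------------
# Canonical key (deduplication only; the chromosome itself stays free-form)
# ---------------------------------------------------------------------------


def canonical_key(graph: MoleculeGraph) -> str:
    """Stereo-agnostic canonical identifier: equal iff two graphs are
    isomorphic as element/bond-order labelled graphs.

    Used only for deduplication in reporting, never as the chromosome.
    Implemented on top of RDKit's canonical ranking with aromaticity
    perception disabled so distinct Kekulé graphs stay distinct.
    """
    from rdkit import Chem

    mol = Chem.RWMol()
    for el in graph.elements:
        mol.AddAtom(Chem.Atom(el))
    btype = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for bond in graph.bonds():
        mol.AddBond(bond.i, bond.j, btype[bond.order])
    flags = (
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
    )
    Chem.SanitizeMol(mol, flags)
    return Chem.MolToSmiles(mol, canonical=True)


# ---------------------------------------------------------------------------
# Ring perception
# ---------------------------------------------------------------------------


def _cycle_edges(graph_nx: nx.Graph, nodes: list[int]) -> tuple[tuple[int, int], ...]:
    """Recover the bond list of a basis cycle given as a node set."""
    node_set = set(nodes)
    sub = graph_nx.subgraph(node_set)
    if all(d == 2 for _, d in sub.degree()):
        return tuple(sorted(tuple(sorted(e)) for e in sub.edges()))
    # Chorded induced subgraph: search for a closed walk through all nodes.
    start = min(node_set)

    def search(path: list[int], used: set[int]) -> Optional[list[int]]:
        u = path[-1]
        if len(path) == len(node_set):
            return path if graph_nx.has_edge(u, start) else None
        for v in sorted(sub.neighbors(u)):
            if v not in used:
                got = search(path + [v], used | {v})
                if got:
                    return got
        return None

    cyc = search([start], {start})
    if cyc is None:  # pragma: no cover - defensive
        raise RuntimeError("could not recover cycle edges from basis node set")
    edges = [tuple(sorted((cyc[k], cyc[(k + 1) % len(cyc)]))) for k in range(len(cyc))]
    return tuple(sorted(edges))


def perceive_rings(graph: MoleculeGraph) -> RingCensus:
    """Smallest-set-of-smallest-rings census.

    ``n_rings`` equals the cyclomatic number (bonds - atoms + 1 for a
    connected graph); each reported ring is a minimum-weight cycle-basis
    element with its bond list; ``ring_bonds`` is the set of all bonds on
    any cycle (consistent with per-bond in_ring flags).
    """
    g = graph.to_networkx()
    n_rings = graph.n_bonds - graph.n_atoms + 1
    if n_rings <= 0:
        return RingCensus(0, tuple(), frozenset())
    basis = nx.minimum_cycle_basis(g)
    rings = tuple(sorted((_cycle_edges(g, cyc) for cyc in basis), key=lambda r: (len(r), r)))
    return RingCensus(n_rings, rings, frozenset(graph.ring_bond_set()))


def ring_bond_census(graph: MoleculeGraph) -> tuple[int, int]:
    """(total ring bonds, bonds whose removal destroys the largest ring).

    The first number is the size of the union of all SSSR ring bonds; the
    second counts the bonds of the largest-membered SSSR ring (ties broken
    deterministically) — exactly the bonds a ring-opening mutation could cut
    to destroy that ring.  Acyclic input returns (0, 0).
    """
    census = perceive_rings(graph)
    if census.n_rings == 0:
        return (0, 0)
    largest = max(census.rings, key=len)
    return (len(census.ring_bonds), len(largest))


# ---------------------------------------------------------------------------
# Stereo elements
# ---------------------------------------------------------------------------


def symmetry_classes(graph: MoleculeGraph) -> list[int]:
    """Atom equivalence classes by iterative neighbourhood refinement
    (Morgan/Weisfeiler-Lehman style).  Two atoms in different classes can
    never be exchanged by a graph automorphism."""
    hs = graph.implicit_h()
    labels: list = [
        (graph.elements[i], len(graph.adj[i]), hs[i], tuple(sorted(graph.adj[i].values())))
        for i in range(graph.n_atoms)
    ]
    n_classes = len(set(labels))
    for _ in range(graph.n_atoms + 1):
        new = [
            (labels[i], tuple(sorted((graph.adj[i][j], labels[j]) for j in graph.adj[i])))
            for i in range(graph.n_atoms)
        ]
        mapping = {lab: k for k, lab in enumerate(sorted(set(new)))}
        labels = [mapping[lab] for lab in new]
        if len(set(labels)) == n_classes:
            break
        n_classes = len(set(labels))
    mapping = {lab: k for k, lab in enumerate(sorted(set(labels), key=repr))}
    return [mapping[lab] for lab in labels]


def find_stereo_elements(
    graph: MoleculeGraph,
) -> tuple[list[int], list[tuple[int, int]]]:
    """Detect the ± stereo basis of a chromosome.

    Tetrahedral centres: atoms with four single-bond substituents (implicit
    H counts as one, at most one H) that are pairwise distinguishable by
    symmetry class.  Stereogenic double bonds: *acyclic* order-2 bonds where
    each end carries two distinguishable substituents (one heavy + one
    implicit H qualifies); double bonds inside rings are excluded — the
    convention that reconciles a macrocyclic drug's 2^5 basis with a chain
    polyene's 2^3.
    """
    classes = symmetry_classes(graph)
    hs = graph.implicit_h()
    ring_bonds = graph.ring_bond_set()

    tetra: list[int] = []
    for i in range(graph.n_atoms):
        deg = graph.heavy_degree(i)
        if deg + hs[i] != 4 or hs[i] > 1:
            continue
        if any(order != 1 for order in graph.adj[i].values()):
            continue
        nbr_classes = [classes[j] for j in graph.adj[i]]
        if len(set(nbr_classes)) == len(nbr_classes):
            tetra.append(i)

    def end_ok(end: int, partner: int) -> bool:
        subs = [j for j in graph.adj[end] if j != partner]
        n_subs = len(subs) + hs[end]
        if n_subs != 2 or len(subs) == 0:  # =CH2 end: two identical hydrogens
            return False
        if len(subs) == 1:  # one heavy + one implicit H: distinguishable
            return True
        return classes[subs[0]] != classes[subs[1]]

    dbs: list[tuple[int, int]] = []
    for bond in graph.bonds():
        if bond.order != 2 or (bond.i, bond.j) in ring_bonds:
            continue
        if end_ok(bond.i, bond.j) and end_ok(bond.j, bond.i):
            dbs.append((bond.i, bond.j))

    return sorted(tetra), sorted(dbs)


def count_stereoisomers(graph: MoleculeGraph) -> int:
    """Uncapped stereoisomer count 2^(tetra centres + acyclic stereo C=C)."""
    tetra, dbs = find_stereo_elements(graph)
    return 2 ** (len(tetra) + len(dbs))


def enumerate_stereoisomers(
    graph: MoleculeGraph, cap: int = 512
) -> list[StereoAssignment]:
    """Expand the chromosome into min(2^k, cap) indexed stereo assignments.

    Assignments are ordered lexicographically over the ± basis (tetra
    centres by atom index first, then double bonds), so "stereoisomer 5 of
    32" is reproducible across runs.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    tetra, dbs = find_stereo_elements(graph)
    k = len(tetra) + len(dbs)
    total = cap if k >= 63 else min(2**k, cap)
    out: list[StereoAssignment] = []
    for idx in range(total):
        bits = [(idx >> (k - 1 - b)) & 1 for b in range(k)] if k else []
        t_par = tuple(
            (atom, "+" if bits[p] == 0 else "-") for p, atom in enumerate(tetra)
        )
        d_cfg = tuple(
            (b, "cis" if bits[len(tetra) + p] == 0 else "trans")
            for p, b in enumerate(dbs)
        )
        out.append(StereoAssignment(index=idx, tetra_parity=t_par, db_config=d_cfg))
    return out


# ---------------------------------------------------------------------------
# Property profile
# ---------------------------------------------------------------------------


def rotatable_dihedrals(graph: MoleculeGraph) -> int:
    """Count rotatable dihedral bonds.

    Convention: a non-ring single bond whose two endpoints each have at
    least two heavy-atom neighbours, excluding carboxamide C(=O)-N bonds.
    This is the unique convention consistent with every printed fixture
    count used in the tests (3 / 7 / 6 / 8).
    """
    ring_bonds = graph.ring_bond_set()
    count = 0
    for bond in graph.bonds():
        if bond.order != 1 or (bond.i, bond.j) in ring_bonds:
            continue
        if graph.heavy_degree(bond.i) < 2 or graph.heavy_degree(bond.j) < 2:
            continue
        if _is_carboxamide(graph, bond.i, bond.j) or _is_carboxamide(graph, bond.j, bond.i):
            continue
        count += 1
    return count


def _is_carboxamide(graph: MoleculeGraph, c: int, n: int) -> bool:
    if graph.elements[c] != "C" or graph.elements[n] != "N":
        return False
    return any(
        order == 2 and graph.elements[j] == "O" for j, order in graph.adj[c].items()
    )


def compute_properties(
    graph: MoleculeGraph,
    masses: Optional[dict[str, float]] = None,
    log_kow: Optional[float] = None,
) -> PropertyProfile:
    """Measure the full ADME-relevant property profile of a molecule.

    ``masses`` must cover the alphabet plus hydrogen (checked up front —
    a missing entry is a configuration error, not a per-molecule failure).
    """
    if masses is None:
        masses = ATOMIC_MASSES
    missing = (set(graph.config.atom_types) | {"H"}) - set(masses)
    if missing:
        raise KeyError(f"mass table missing entries for {sorted(missing)}")

    hs = graph.implicit_h()
    mass = sum(masses[el] for el in graph.elements) + masses["H"] * sum(hs)
    hbd = sum(
        1 for i, el in enumerate(graph.elements) if el in ("N", "O") and hs[i] >= 1
    )
    hba = sum(1 for el in graph.elements if el in ("N", "O"))
    tetra, dbs = find_stereo_elements(graph)
    ring_bonds = graph.ring_bond_set()
    return PropertyProfile(
        heavy_atoms=graph.n_atoms,
        molecular_mass=mass,
        hbd=hbd,
        hba=hba,
        rotatable_dihedrals=rotatable_dihedrals(graph),
        n_rings=graph.n_bonds - graph.n_atoms + 1,
        n_ring_bonds=len(ring_bonds),
        n_tetra_centers=len(tetra),
        n_stereo_dbs=len(dbs),
        log_kow=log_kow,
    )
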