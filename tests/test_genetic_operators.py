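"""Validity closure and semantics of crossover and the 14 mutations."""

from collections import Counter

import numpy as np
import pytest

from smilesga.fixtures import REGISTRY
from smilesga.genetic_operators import (
    MutationKind,
    OperatorConfig,
    OperatorFailure,
    add_atom,
    add_branch,
    apply_mutation,
    change_atom,
    change_bond_order,
    classify_segment,
    close_ring,
    crossover,
    crossover_at,
    delete_atom,
    delete_branch,
    interchange_dihedral,
    mutate,
    open_ring,
)
from smilesga.molgraph import (
    canonical_key,
    parse_smiles,
    perceive_rings,
    write_smiles,
)

BENZENE = "C1=CC=CC=C1"


def formula(graph) -> Counter:
    return Counter(graph.elements)


def one_hot(kind: MutationKind, **overrides) -> OperatorConfig:
    return OperatorConfig(
        unnorm_mut_probability={k: (1.0 if k is kind else 0.0) for k in MutationKind},
        **overrides,
    )


# ---------------------------------------------------------------------------
# Segments and crossover
# ---------------------------------------------------------------------------


class TestSegments:
    def test_branch_atom(self):
        span = classify_segment(parse_smiles("CC(O)C"), 2)
        assert span.kind == "branch" and span.atoms == frozenset({2})

    def test_tail_atom(self):
        span = classify_segment(parse_smiles("CCCC"), 2)
        assert span.kind == "tail" and span.atoms == frozenset({2, 3})

    def test_every_ring_atom_is_blocked(self):
        g = parse_smiles(BENZENE)
        assert all(classify_segment(g, i).kind == "ring-blocked" for i in range(6))


class TestCrossover:
    def test_forced_tail_swap(self):
        a, b = parse_smiles("CCCO"), parse_smiles("CCN")
        child_a, child_b = crossover_at(a, 3, b, 2)
        assert canonical_key(child_a) == canonical_key(parse_smiles("CCCN"))
        assert canonical_key(child_b) == canonical_key(parse_smiles("CCO"))

    def test_two_benzenes_return_unmodified_copies(self, rng):
        g = parse_smiles(BENZENE)
        cfg = OperatorConfig(min_heavy_atoms=3)
        child_a, child_b = crossover(g, g, cfg, rng)
        assert canonical_key(child_a) == canonical_key(g)
        assert canonical_key(child_b) == canonical_key(g)

    def test_small_children_replaced_by_parent_copies(self, rng):
        a, b = parse_smiles("CCCCCCCCCCCC"), parse_smiles("CCCCCCCCCCC")
        cfg = OperatorConfig(min_heavy_atoms=10)
        for _ in range(50):
            child_a, child_b = crossover(a, b, cfg, rng)
            assert child_a.n_atoms >= 10 and child_b.n_atoms >= 10

    def test_heavy_atom_total_conserved_when_both_swaps_succeed(self):
        a, b = parse_smiles("CCC(N)CO"), parse_smiles("CCOCC")
        for atom_a in range(1, a.n_atoms):
            for atom_b in range(1, b.n_atoms):
                child_a, child_b = crossover_at(a, atom_a, b, atom_b)
                assert child_a.n_atoms + child_b.n_atoms == a.n_atoms + b.n_atoms

    def test_fuzz_children_always_valid(self, rng):
        a = REGISTRY["aspirin"].parse()
        b = REGISTRY["aspirin_edited"].parse()
        cfg = OperatorConfig(min_heavy_atoms=5)
        for _ in range(300):
            for child in crossover(a, b, cfg, rng):
                parse_smiles(write_smiles(child))  # parses + valence-valid


# ---------------------------------------------------------------------------
# Individual mutations
# ---------------------------------------------------------------------------


class TestAtomMutations:
    def test_change_atom_forced_to_oxygen(self, rng):
        cfg = OperatorConfig(
            unnorm_percent_atom={"C": 0, "N": 0, "O": 1, "P": 0, "S": 0, "F": 0},
            min_heavy_atoms=1,
        )
        out = change_atom(parse_smiles("CC"), cfg, rng)
        assert canonical_key(out) == canonical_key(parse_smiles("CO"))

    def test_change_atom_respects_valence(self, rng):
        # F (valence 1) can never replace a double-bonded carbon
        cfg = OperatorConfig(
            unnorm_percent_atom={"C": 0, "N": 0, "O": 0, "P": 0, "S": 0, "F": 1},
            min_heavy_atoms=1,
        )
        with pytest.raises(OperatorFailure):
            change_atom(parse_smiles("C=C"), cfg, rng)

    def test_add_atom_changes_count_by_one(self, rng):
        cfg = OperatorConfig(min_heavy_atoms=1)
        g = parse_smiles("CC")
        for _ in range(30):
            out = add_atom(g, cfg, rng)
            assert out.n_atoms == 3
            parse_smiles(write_smiles(out))

    def test_add_atom_splice_produces_ether(self, rng):
        cfg = OperatorConfig(
            unnorm_percent_atom={"C": 0, "N": 0, "O": 1, "P": 0, "S": 0, "F": 0},
            min_heavy_atoms=1,
        )
        seen = set()
        for _ in range(60):
            seen.add(canonical_key(add_atom(parse_smiles("CC"), cfg, rng)))
        assert canonical_key(parse_smiles("COC")) in seen  # splice mode reached

    def test_delete_atom_middle_of_ether(self, rng):
        cfg = OperatorConfig(min_heavy_atoms=1)
        seen = set()
        for _ in range(40):
            seen.add(canonical_key(delete_atom(parse_smiles("COC"), cfg, rng)))
        assert canonical_key(parse_smiles("CC")) in seen
        assert all(
            k in {canonical_key(parse_smiles(s)) for s in ("CC", "CO")} for k in seen
        )

    def test_delete_respects_min_heavy_atoms_via_dispatcher(self, rng):
        cfg = one_hot(MutationKind.DELETE_ATOM, min_heavy_atoms=10)
        g = parse_smiles("CCC")
        out = mutate(g, cfg, rng)  # input already below the floor: allowed
        assert out.n_atoms in (2, 3)
        big = parse_smiles("C" * 10)
        assert mutate(big, cfg, rng).n_atoms == 10  # identity, floor binds


class TestBranchMutations:
    def test_add_branch_on_chain_interior(self, rng):
        cfg = OperatorConfig(
            unnorm_percent_atom={"C": 0, "N": 0, "O": 1, "P": 0, "S": 0, "F": 0},
            min_heavy_atoms=1,
        )
        out = add_branch(parse_smiles("CCC"), cfg, rng)
        assert canonical_key(out) == canonical_key(parse_smiles("CC(O)C"))

    def test_delete_branch_removes_whole_subtree(self, rng):
        cfg = OperatorConfig(min_heavy_atoms=1)
        g = parse_smiles("CC(OC)CC")
        keys = {canonical_key(delete_branch(g, cfg, rng)) for _ in range(60)}
        assert canonical_key(parse_smiles("CCCC")) in keys  # OC excised whole

    def test_delete_branch_fails_on_unbranched_chain(self, rng):
        with pytest.raises(OperatorFailure):
            delete_branch(parse_smiles("CCC"), OperatorConfig(min_heavy_atoms=1), rng)


class TestRingMutations:
    def test_close_ends_of_hexane(self, rng):
        cfg = OperatorConfig(min_heavy_atoms=1)
        keys = {canonical_key(close_ring(parse_smiles("CCCCCC"), cfg, rng))
                for _ in range(80)}
        assert canonical_key(parse_smiles("C1CCCCC1")) in keys

    def test_open_benzene_gives_hexatriene(self, rng):
        out = open_ring(parse_smiles(BENZENE), OperatorConfig(min_heavy_atoms=1), rng)
        assert canonical_key(out) == canonical_key(parse_smiles("C=CC=CC=C"))

    def test_ring_count_changes_by_exactly_one(self, rng):
        cfg = OperatorConfig(min_heavy_atoms=1)
        g = parse_smiles("C1CCCCC1CCCC")
        n0 = perceive_rings(g).n_rings
        closed = close_ring(g, cfg, rng)
        assert perceive_rings(closed).n_rings == n0 + 1
        opened = open_ring(g, cfg, rng)
        assert perceive_rings(opened).n_rings == n0 - 1

    def test_open_ring_failure_on_acyclic(self, rng):
        with pytest.raises(OperatorFailure):
            open_ring(parse_smiles("CCCC"), OperatorConfig(min_heavy_atoms=1), rng)

    def test_open_ring_hits_macrocycle_at_closure_rate(self, simeprevir, rng):
        """Uniform choice over the chromosome's 7 ring closures opens the
        largest ring in about 1/7 of draws (Monte-Carlo vs the ring census)."""
        cfg = OperatorConfig(min_heavy_atoms=1)
        largest_before = max(perceive_rings(simeprevir).ring_sizes())
        n, hits = 700, 0
        for _ in range(n):
            out = open_ring(simeprevir, cfg, rng)
            if max(perceive_rings(out).ring_sizes()) < largest_before:
                hits += 1
        assert abs(hits / n - 1 / 7) < 0.05


class TestBondOrderMutations:
    def test_single_to_double(self, rng):
        op = change_bond_order(1, 2)
        out = op(parse_smiles("CC"), OperatorConfig(min_heavy_atoms=1), rng)
        assert canonical_key(out) == canonical_key(parse_smiles("C=C"))

    def test_double_to_triple(self, rng):
        op = change_bond_order(2, 3)
        out = op(parse_smiles("C=C"), OperatorConfig(min_heavy_atoms=1), rng)
        assert canonical_key(out) == canonical_key(parse_smiles("C#C"))

    def test_raising_requires_free_valence_on_both_ends(self, rng):
        op = change_bond_order(1, 3)
        with pytest.raises(OperatorFailure):
            op(parse_smiles("CC(C)(C)C"), OperatorConfig(min_heavy_atoms=1), rng)


class TestInterchangeDihedral:
    def test_formula_conserved_and_valid(self, rng):
        cfg = OperatorConfig(min_heavy_atoms=1)
        g = REGISTRY["aspirin_edited"].parse()
        for _ in range(300):
            out = interchange_dihedral(g, cfg, rng)
            assert formula(out) == formula(g)
            parse_smiles(write_smiles(out))

    def test_branch_swap_changes_connectivity(self, rng):
        g = parse_smiles("CC(O)C(N)CC")
        keys = {canonical_key(interchange_dihedral(
            g, OperatorConfig(min_heavy_atoms=1), rng)) for _ in range(60)}
        assert canonical_key(parse_smiles("CC(N)C(O)CC")) in keys

    def test_failure_without_substituents(self, rng):
        with pytest.raises(OperatorFailure):
            interchange_dihedral(parse_smiles("CC"), OperatorConfig(min_heavy_atoms=1), rng)


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------


class TestDispatcher:
    def test_forced_kind_is_applied(self, rng):
        cfg = one_hot(
            MutationKind.CHANGE_ATOM,
            unnorm_percent_atom={"C": 0, "N": 0, "O": 1, "P": 0, "S": 0, "F": 0},
            min_heavy_atoms=1,
        )
        out = mutate(parse_smiles("CC"), cfg, rng)
        assert canonical_key(out) == canonical_key(parse_smiles("CO"))

    def test_total_failure_returns_identity(self, rng):
        cfg = one_hot(MutationKind.OPEN_RING, min_heavy_atoms=1)
        g = parse_smiles("CCCC")
        out = mutate(g, cfg, rng)
        assert canonical_key(out) == canonical_key(g)

    def test_identical_seed_gives_identical_sequence(self, aspirin):
        cfg = OperatorConfig()
        seqs = []
        for _ in range(2):
            r = np.random.default_rng(99)
            g = aspirin
            seq = []
            for _ in range(40):
                g = mutate(g, cfg, r)
                seq.append(write_smiles(g))
            seqs.append(seq)
        assert seqs[0] == seqs[1]

    def test_validity_closure_under_default_weights(self, aspirin, rng):
        cfg = OperatorConfig()
        g = aspirin
        for _ in range(400):
            g = mutate(g, cfg, rng)
            again = parse_smiles(write_smiles(g))
            assert g.is_isomorphic(again)
            assert g.n_atoms >= min(cfg.min_heavy_atoms, aspirin.n_atoms)
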