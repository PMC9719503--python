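# Methods

This note documents the models, conventions and numerical choices behind
`smilesga`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, with
which defaults, and what the shipped tests do and do not demonstrate.

## Chromosomes and the valence model

A chromosome is a non-isomeric SMILES string in Kekulé form over the
alphabet C, N, O, P, S, F with fixed valences 4, 3, 2, 3, 2, 1.  There
are no aromatic tokens, formal charges or isotopes anywhere in the
package: aromatic rings are carried as explicit alternating bonds, which
keeps every operator's feasibility test a pure valence arithmetic.
Implicit hydrogens fill each atom's remaining valence.

Sulfur is the one asymmetry: real drug molecules contain sulfonamide
S(=O)(=O) groups, so the **parser accepts S at valence 2, 4 or 6**
(choosing the smallest valence that fits when assigning hydrogens), while
the **mutation operators only ever create S at valence 2**.  Input
tolerance without operator hypervalence lets such molecules evolve
without the GA inventing exotic sulfur chemistry.

Parsing failures — syntax errors, unmatched ring digits, valence
violations — raise a dedicated error hierarchy that the evaluation layer
converts into the failure-sentinel fitness; a malformed individual never
crashes a run.

Serialisation walks a deterministic DFS (neighbours in ascending index
order) and freshly numbers ring-closure digits 1, 2, … in traversal
order, so the textual chromosome is regenerated (and ring digits
renormalised) after every graph edit.  Round-tripping is guaranteed up to
graph isomorphism and is property-tested.

One stored fixture is repaired: the edited aspirin-derived design
circulates with a double-bond misprint that makes a ring carbon
pentavalent; the registry stores the fulvene-style placement consistent
with the molecule's described structure.  Every counted property (19
heavy atoms, 7 rotatable bonds) is unaffected by the repair.

## Canonical keys

Chromosomes are deliberately *not* canonicalised during evolution —
multiple SMILES spellings of one molecule are distinct search states, and
collapsing them would restrict the walk.  A canonical key exists solely
for deduplication in reports.  It is computed through RDKit's canonical
ranking with aromaticity perception disabled, so two graphs share a key
exactly when they are isomorphic as element/bond-order labelled graphs
(stereo ignored).  The tests cross-check this iff-property against
explicit VF2 isomorphism on a mixed sample.

## Rings

Ring perception uses a minimum cycle basis (networkx), the SSSR
convention: the number of rings equals the cyclomatic number
`bonds − atoms + 1`, and the basis rings are the smallest independent
cycles.  Per-bond ring membership uses the bridge criterion (a bond is a
ring bond iff its removal keeps the graph connected), which coincides
with the union of SSSR ring bonds on molecular graphs.  The ring-bond
census reports (total ring bonds, bonds of the largest SSSR ring); for
the simeprevir fixture this is (39, 14) — a 14-bond macrocycle plus six
smaller rings with three fusion bonds counted once, independently
confirmed by RDKit's ring perception.  The test suite also checks the
basis sizes against a brute-force Horton/GF(2) oracle on dozens of small
random graphs.

## Stereo convention

The stereo basis of a chromosome consists of

* **tetrahedral centres** — atoms with four single-bonded substituents
  (implicit H counts as one, at most one H) that are pairwise
  distinguishable, and
* **acyclic stereogenic double bonds** — order-2 bonds outside rings
  whose ends each carry two distinguishable substituents (one heavy atom
  plus one implicit H qualifies).

Double bonds *inside* rings are excluded.  This is the one assignment
consistent with both reference counts at once: the macrocyclic drug's
2^5 = 32 basis despite its in-ring C=C, and the chain polyene's 2^3 = 8
from double bonds alone.  Substituent distinguishability is decided by
iterative neighbourhood refinement (Morgan/Weisfeiler–Lehman classes);
this is exact in practice for drug-sized molecules and agrees with
RDKit's stereocentre perception on every fixture, but, like all
refinement-based symmetry detection, it can in principle miss an
automorphism that only exists globally (it would then over-count centres
in highly symmetric cages).  Meso relationships between assignments are
not detected: the basis is enumerated as all 2^k sign combinations, in
lexicographic order, capped at `max_stereoisomers` (default 512), and
each assignment is indexable ("stereoisomer 5 of 32") and reproducible.

## Rotatable dihedral bonds

No universal convention exists; the one used here is: **a non-ring single
bond whose endpoints both have at least two heavy neighbours, excluding
carboxamide C(=O)–N bonds**.  It reproduces all four reference counts
simultaneously (aspirin 3, edited design 7, the acryloyl variant 6,
simeprevir 8); sulfonamide N–S bonds are counted, which the reference
values require.

## ADME penalties

`P_ADME` checks mass ≤ 500 Da, donors (N/O with ≥ 1 H) ≤ 5, acceptors
(N+O count) ≤ 10, rotatable dihedrals ≤ 7 and, only when a user supplies
one, log K_ow ≤ 5 (the partition coefficient is never computed — it is an
input hook).  Soft mode charges `coeff × max(0, (x − limit)/limit)` per
rule; the *relative* violation keeps penalties commensurate with
surrogate scores of order 10–100 (coefficients 4, 10, 10, 10 would
otherwise dwarf any score at modest mass violations); the raw
`coeff × (x − limit)` form is available behind `relative_soft: false`.
Hard mode charges a flat 20 per violated rule.  The classic N+O acceptor
count gives 12 for simeprevir where pharmacophore-style counting gives
the quoted 10; profiles therefore accept explicit overrides when a
published profile must be reproduced.

Note the documented sharp edge: the failure sentinel 0 can be *better*
than a valid positive fitness when penalties exceed the score.  This is
the method's defined behaviour and is not clamped.

## Genetic operators

Crossover follows the chromosome text's segment semantics.  In the
serialisation DFS tree, the span "from an atom to the end of its
enclosing branch (or expression)" is exactly the subtree rooted at that
atom; an atom on a ring is ring-blocked (one cut cannot split a ring) and
is re-drawn, up to `max_tries` (default 20) per parent.  Exchanged
segments reattach with the receiving parent's original bond order (string
splice semantics); children failing validation or falling below
`min_heavy_atoms` (default 10) are replaced by parent copies, and total
failure returns unmodified copies — never an exception.

Mutations are dispatched by normalised named weights (uniform by
default).  Site selection is uniform over feasible sites; element draws
use the configured per-element weights restricted to valence-feasible
elements, which naturally leans the composition toward carbon.  Design
choices where the operator semantics were open:

* CLOSE_RING is purely topological — two unbonded free-valence atoms at
  graph distance 2–7, creating a 3–8-membered ring.  The tabulated
  inter-atomic bond lengths with the 1.10 cutoff factor are honoured as
  an optional geometric post-filter (`bond_length_ok`) that only applies
  when a 3D-capable scorer supplies coordinates; the core is 3D-free.
* OPEN_RING removes one of the chromosome's own ring-closure bonds (the
  digit pairs of its traversal), not an arbitrary ring bond — uniform
  over closures, so a 7-ring molecule's macrocycle closure is hit with
  probability 1/7 (Monte-Carlo-tested).  General ring-bond scission
  (OPEN_BOND) is deliberately absent from this operator set.
* INTERCHANGE_DIHEDRAL is read as a branch swap across an acyclic bond
  (exchange one substituent branch from each side).  A non-isomeric
  chromosome has no cis/trans state to flip, so this is the rewiring
  interpretation that preserves the molecular formula; that conservation
  is property-tested.
* DELETE_ATOM on a degree-2 ring atom reconnects its neighbours with a
  single bond, shrinking the ring by one — the intended mechanism for
  shortening large rings without opening them.
* ADD_BRANCH seeds single-atom branches; longer branches arise over
  iterations.

Every operator is closed under validity (output parses, satisfies the
valence model, stays connected), enforced by construction and re-checked
by ~10^4-draw fuzz tests.

## The generational loop

Selection default is stochastic-uniform sampling over rank-based weights
(`w ∝ 1/√rank`, ties sharing their rank-span average) — raw fitnesses are
negative, so a sign-safe, scale-free mapping is required; roulette and
k=2 tournament are also provided.  A population whose every fitness is
the sentinel 0 falls back to uniform selection with a warning.  Elites
(`round(0.1 × pop)`) are copied unchanged and not re-scored under a
deterministic scorer, making the best-fitness trace non-increasing; the
`reevaluate_elites` flag restores the non-monotone behaviour a stochastic
docking backend produces.  Crossover (0.8) and mutation (0.8) are
independent per-slot probabilities — fractions summing past 1 cannot be
complementary.  Termination: generation budget (100) or best-fitness
improvement below `tol_fun` (0.02) for `stall_gen_limit` (100)
generations.  `tol_con` is accepted in configuration but inert:
constraints enter as penalties, no constraint solver is used.

Checkpoints are versioned JSON containing every generation's records and
the RNG state captured after producing it, so killing a run and resuming
from its checkpoint replays the remaining generations bit-for-bit (an
asserted invariant, as is byte-identical history under identical seeds).

## The surrogate site

The deterministic surrogate scores a molecule by the weighted L1 distance
between its structural profile (heavy atoms, donors, acceptors, rings,
rotatable dihedrals) and a target profile: `max(0, s_max − Σ w_i |p_i −
t_i|)`, with `s_max = 100` so scores sit in the 0–100 range of typical
docking scores.  It emulates the *shape* of the problem — a smooth,
bounded objective over molecule space with a known optimum — which is
what the loop, penalties, checkpointing and reports need to be exercised
reproducibly.  It does **not** emulate pose geometry, pharmacophore
complementarity, score noise, or the ruggedness of real docking
landscapes, so passing tests demonstrate the correctness of the
evolutionary machinery, not binding-affinity prediction.  Interaction
reports (hydrogen-bond records for the constraint hooks) can be emitted
synthetically; scores are stereo-independent by construction, so
per-stereoisomer differentiation is exercised through the replay scorer
instead.

## Test problem sizes

The shipped suites use populations of 10–50, 5–50 generations, ~10^4
operator fuzz draws and 3-seed convergence replicates: sizes chosen so
the whole suite runs in about a minute on one core while every asserted
property (validity closure, 2^k law, elitism monotonicity, seeded
determinism, convergence to within 10% of the surrogate optimum from
random C4–C6 alkanes, the soft-ADME restriction contrast, restart replay)
is exercised end-to-end.  The contrast harness uses a surrogate whose
optimum violates the rule-of-5 limits, so the restricted run measurably
trails the unrestricted one on the same seed — the qualitative behaviour
expected when constraining an evolution whose unconstrained optimum is
non-compliant.

## Known limitations

* No aromaticity, tautomers, charges or pH states; no 2D/3D depiction.
* log K_ow is input-only; no estimator is bundled.
* External docking engines are supported as a scorer contract and
  configuration descriptor only; no engine ships with the package.
* Symmetry classes from iterative refinement are a (tight) approximation
  of automorphism orbits; pathological symmetric cages could over-count
  stereocentres.
* The multi-objective / multi-protein generalisation of the method is out
  of scope: the objective is a single scalar.
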