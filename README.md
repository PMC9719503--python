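# smilesga

A genetic algorithm over SMILES chromosomes for de novo ligand design.

Finding a small molecule that binds a given protein site is a search over
a space of roughly 10^80 candidate organic structures — far beyond any
screening database. `smilesga` searches that space directly: molecules are
carried as **textual chromosomes** (non-isomeric Kekulé SMILES over the
alphabet C, N, O, P, S, F), evolved by chemistry-aware crossover and
fourteen named mutation operators (atom change/insertion/deletion, branch
growth/excision, ring closing/opening, dihedral-branch interchange, and
six bond-order transitions), and ranked by a binding-site fitness under
ADME, substructure and interaction constraints.  It is aimed at
computational chemists prototyping GA-driven hit generation and at anyone
who needs a fully reproducible, docking-free testbed for molecular
evolutionary algorithms.

## The fitness model

Each chromosome *c* is expanded into its stereoisomer basis (tetrahedral
centres and acyclic stereogenic double bonds; 2^k assignments, capped at
512).  Every stereoisomer is scored by a pluggable backend, and

```
F(c) = − max_s score(c, s) + P_ADME(c) + P_substructure(c) + P_hbond(c) + P_localization(c)
```

is minimised (**negative is better**); a chromosome that cannot be parsed
or scored receives the failure sentinel `F = 0` and is ejected by
selection.  `P_ADME` implements soft/hard Lipinski rule-of-5 limits (mass
≤ 500 Da, donors ≤ 5, acceptors ≤ 10, optional log K_ow ≤ 5) plus a
rotatable-dihedral limit (≤ 7); the other penalties hook forbidden
substructures (e.g. enol ethers), required hydrogen bonds to named
residues, and 3D localization of the pose.

Scoring is a contract: the shipped backends are a **deterministic
surrogate site** (score = `max(0, s_max − Σ w_i |p_i − t_i|)` over a
structural property profile) and a file-based replay scorer; an external
docking engine can plug in behind the same interface.

## Worked example

Property profile of aspirin and the stereo basis of the macrocyclic drug
simeprevir:

```bash
$ smilesga props "CC(=O)OC1=CC=CC=C1C(=O)O"
heavy_atoms 13
molecular_mass 180.159
hbd 1
hba 4
rotatable_dihedrals 3
n_rings 1
...

$ smilesga stereo "CC1=C(C=CC2=C1N=C(...)C7=NC(=CS7)C(C)C)OC"   # simeprevir
stereoisomers 32 (enumerated 32, cap 512)
```

Aspirin has 13 heavy atoms, one H-bond donor, four N+O acceptors and
three rotatable dihedral bonds — comfortably rule-of-5 compliant.
Simeprevir's five tetrahedral stereocentres give a 2^5 = 32-point ± basis
(its macrocyclic double bond is excluded by convention).

A complete GA run against the surrogate site, from a population of 21
random butanes/pentanes/hexanes toward a 19-heavy-atom monocycle:

```yaml
# run.yaml
paths: {initial_population: pop.smi, checkpoint_out: run.json}
ga: {generations: 30, seed: 1}
molecular: {min_heavy_atoms: 4}
scorer:
  type: synthetic
  target: {heavy_atoms: 19, n_rings: 1}
  weights: {heavy_atoms: 4.0, n_rings: 10.0}
  s_max: 100
```

```bash
$ smilesga run --config run.yaml
finished after 31 recorded generations; final best -100.0000, mean -66.1905
$ smilesga report run.json | head -2
canonical_key	smiles	best_fitness	first_seen_generation	heavy_atoms	...
C#CCSCCC1CC1C#CCC(CCC)C(C)P	C#CCSCCC1CC1C#CCC(CCC)C(C)P	-100.0	24	19	...
```

The best fitness of −100 means the population reached the surrogate
optimum (a valid 19-atom, one-ring molecule) exactly; the sorted-unique
report lists every distinct molecule ever seen, deduplicated by canonical
key, best first.  Runs checkpoint every generation (including RNG state),
so a killed run restarts bit-for-bit identically, and `smilesga evaluate`
scores any SMILES list standalone.

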