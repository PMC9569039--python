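# rnadel

Design of **deleterious multi-point RNA mutations** — substitutions,
insertions and deletions — that rearrange an RNA's minimum-free-energy (MFE)
secondary structure toward distant alternative folds.

Functional RNAs (viral replication elements, ribozymes, riboswitches) act
through their secondary structure. A mutation set that forces a global
conformational rearrangement is expected to disrupt function, which makes
such sets valuable for site-directed mutagenesis: `rnadel` proposes a
user-bounded number *N* of *M*-point mutation sets ranked by how far the
mutant refolds from the wild-type structure. It is aimed at molecular
biologists and virologists planning disruption experiments, and at RNA
bioinformaticians studying mutational robustness.

## Method

Let *w* be an RNA sequence with MFE structure *S₀*. The pipeline:

1. **Fold** — compute *S₀* and stream all suboptimal structures within
   *e* kcal/mol of the MFE (ViennaRNA's RNAfold/RNAsubopt model).
2. **Filter** — drop structures within distance *d₁* of *S₀*; sort the rest
   by distance descending and greedily keep structures pairwise more than
   *d₂* apart. The survivors are a small set of diverse, distant
   representatives. Distances are positionwise dot-bracket (Hamming)
   distances.
3. **Collect candidates** — for each representative *S̄*, find single-point
   mutations that *stabilize* *S̄* (deleting/substituting/inserting in the
   bulges and interior loops between its stems, creating Watson–Crick pairs
   that merge helices) or *destabilize* *S₀* (breaking or bulging its
   helices).
4. **Assemble** — combine candidates into sets of exactly *M* mutations at
   distinct positions, at most ⌊N/k⌋(+1) sets per representative, by a
   seeded randomized recursion that mixes mutation types.
5. **Validate and rank** — refold every mutant, project its structure back
   onto wild-type coordinates (pairs touching inserted bases are dropped),
   and keep sets whose projected distance from *S₀* is large enough;
   report them sorted by that distance.

Mutations are named in wild-type coordinates: `G4C` (substitution), `U4`
(deletion), `15A` (insertion of A before position 15), joined as e.g.
`29G-C39-A50-G77`.

The package also contains an executable account of why exact optimization
here is hard (`rnadel.hardness`): under a simplified pair-counting energy
model, choosing the most deleterious substitution set contains max-cut
(**MaxCoCycle**) as a special case, via a reduction that this package tests
against brute-force solvers of both problems. A dependency-light
pair-counting folding engine (`engine="simple"`) built on the same model
makes the entire pipeline runnable and exactly testable without
thermodynamic parameters.

## Worked example

Discovering candidate mutations for a 17-nt toy (optimal structure vs one
distant suboptimal):

```bash
python examples/03_candidate_discovery.py
```

```
== substitutions + insertions ==
seq GAGGGUCGCCUCCGCGC
opt ((((....)))).....
sub ..(.(.((....))).)
     2C  DESTABILIZE_OPT  opt stem (1, 12)
    G4C  BOTH             sub gap (3, 17)/(5, 15); opt stem (1, 12)
    15A  STABILIZE_SUB    sub gap (5, 15)/(7, 14)
   G16C  STABILIZE_SUB    sub gap (3, 17)/(5, 15)
```

`G4C` replaces the G that closes the optimal helix's innermost pair with its
partner's base (shortening that helix) *and* pairs position 4 with position
16 across the suboptimal structure's interior loop (zipping two of its stems
together) — hence role `BOTH`. `15A` inserts a complementary base on the
narrow side of an asymmetric loop. Applying `G4C-15A` gives the mutant
`GAGCGUCGCCUCCGACGC`, whose suboptimal-derived fold `..((((((....))))))`
outcompetes the original optimal structure.

A full prediction run on the bundled 93-nt benchmark
(`python examples/01_predict_mutation_sets.py`) prints:

```
wild type MFE: -54.80 kcal/mol
suboptimal representatives after filtering: 6
validated mutation sets: 16

name	energy	distance
C39A-55A-U59A-89U	-50.00	42
C39A-U45A-55A-89U	-49.80	42
...
```

i.e. 16 validated 4-point sets (mixing substitutions, insertions and
deletions), led by mutants whose refolded structures differ from the
wild-type MFE structure at 42 of 93 positions.

The same pipeline is scriptable from the shell:

```bash
rnadel run --seq GAGGGUCGCCUCCGCGC -M 2 -N 10 --engine simple \
    --dist1 4 --dist2 2 --e-range 1 --validation-threshold 1
rnadel experiment --n-seqs 3 --length 200   # indels-vs-substitutions contrast
rnadel hardness-demo k4.txt                 # max-cut correspondence
```

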