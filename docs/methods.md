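# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `rnadel`. It is the package's own account of its
science; every empirical statement below is recomputed by the test suite or
by `scripts/acceptance.py`.

## Model and problem statement

An RNA secondary structure is a set of base pairs over positions 1..n with
each position in at most one pair; pipeline structures are additionally
non-crossing (pseudoknot-free), while the theory module only requires
position-disjointness. A *deleterious M-point mutation set* is an edit
script of M single-point edits (substitution, insertion, deletion) at
distinct wild-type positions whose mutant refolds into a structure far from
the wild-type MFE structure.

The pipeline does not search the full script space (see *Hardness* below).
Instead it follows the stabilize/destabilize heuristic: start from distant
suboptimal structures of the wild type and propose mutations that make one
of them the new ground state — stabilizing its helices and destabilizing
the wild-type MFE helices.

## Distance kernel

All pipeline distances are **positionwise dot-bracket (Hamming) distances**:
the number of positions whose pairing state — opening, closing, or
unpaired — differs between the two structures. The bundled 93-nt benchmark
table is reproduced exactly by this kernel (distances 43, 39, 39, 36, 35,
34) and *not* by the set-based symmetric-difference base-pair distance
(which gives 40, 49, 48, 41, 39, 34); the Hamming kernel is therefore the
one used for filtering, validation and ranking. `bp_distance` (symmetric
difference) remains available and is used by the theory-module tests. Both
are metrics on equal-length structures.

Indel mutants have a different length than the wild type. Their structures
are compared after **projection to wild-type coordinates**: every mutant
position maps to its originating wild-type position; pairs with an endpoint
on an inserted base are dropped; deleted positions become unpaired in the
projection. This is the simplest monotone choice; an alignment-based
matching would be a possible extension.

## Folding engines

Two engines share one contract (`fold_mfe`, `subopt`, `subopt_sample`):

* **thermodynamic** — ViennaRNA at default parameters. MFE folding through
  the Python bindings; complete suboptimal enumeration streamed from the
  `RNAsubopt` executable. Results (representative structures, survivor
  counts) are sensitive to the ViennaRNA parameter version; the engine
  version is recorded in run metadata and the tests pin the installed one
  (2.7.x). Energies in kcal/mol.
* **simple** — pair-counting model: E(w, S) = −|{(x, y) ∈ S :
  {w_x, w_y} ∈ B}| with B = {AU, CG, GU}; non-canonical pairs contribute
  nothing. The pipeline engine additionally enforces hairpin loops ≥ 3
  unpaired bases for steric realism; the theory module uses the
  unconstrained model. MFE = Nussinov-style maximum canonical-pair fold
  (O(n³) dynamic program, numpy-vectorized inner loop). Energies are
  integers (−pair count) and are never compared across engines.

Ties among co-optimal simple-engine structures are broken deterministically:
the traceback pairs the leftmost undecided position with its nearest
admissible partner whenever some optimal completion pairs it. Tests assert
optimality of the pair count against exhaustive enumeration, not a specific
co-optimal structure.

`subopt` (simple) enumerates *exactly* the structures within an integer
pair-count slack of the maximum, by budgeted backtracking of the DP table;
it is exhaustive whenever consumed in full and is validated against brute
force for n ≤ 12. `enumerate_all_structures` (the test oracle) is guarded
at n ≤ 25; its counts are cross-checked against an independent
Motzkin-style recurrence.

**Sampled streams.** Complete ensembles of random 100–200-nt sequences at
the default energy band are astronomically large, and both engines' exact
enumerations are depth-first, so a truncated prefix is unrepresentative.
When a consumption cap (`max_subopt`) is set, the pipeline therefore draws
from `subopt_sample`: seeded Boltzmann stochastic backtracking filtered to
the energy band (thermodynamic; `RNA.init_rand` makes it reproducible, at
the cost of using process-global RNG state — not thread-safe), or a
restarted randomized exact enumeration (simple; a fresh sub-seed every few
structures spreads the sample across the band). Uncapped runs — including
the 93-nt benchmark reproduction — consume the complete enumeration.

## Filter

Stage 1 removes every suboptimal structure whose distance from the optimal
one is ≤ `dist1` (*strictly greater* survives). Stage 2 sorts survivors by
that distance, descending (ties by lexicographic dot-bracket), and scans
greedily, keeping a structure iff its distance to every kept representative
is > `dist2`. Farthest-first greedy selection is an interpretation — the
underlying idea of "one representative per cluster of similar structures"
does not prescribe an algorithm — chosen for determinism and O(k²) cost.
Strict thresholds reproduce the benchmark's six survivors under ViennaRNA
2.7.x; with non-strict thresholds eight survive. Stage 1 is streaming;
only survivors are buffered.

Defaults: `dist1 = dist2 = round(0.30 n)`, `e_range = round(0.15 n)` — the
suggested settings of roughly 30% / 15% of sequence length — all
overridable.

## Candidate mutations

Stems (maximal stacks of consecutive pairs) are extracted from the optimal
and each representative suboptimal structure. A *stem gap* is the unpaired
region between two coaxially nested consecutive stems (bulge or interior
loop); multiloop branch points form no gap.

**Stabilizers** (per gap of the suboptimal structure, the "good places
between stems"):

* DEL at every gap position (merges the flanking helices);
* SUB at aligned loop slots (t-th 5'-gap position opposite the
  t-th-from-last 3'-gap position, up to the shorter gap's length): replace
  with the Watson–Crick complement of the facing base, skipped when the
  slot already pairs canonically. The t-vs-t-from-last alignment
  generalizes the 1×1 interior-loop case exhibited by the worked example;
* INS on the narrow side of an asymmetric gap, adjacent to the outer
  stem's closing base: one candidate per unmatched wide-side base, inserting
  its Watson–Crick complement.

Designed stabilizers use Watson–Crick complements only; wobble G·U is never
*introduced* but does count as pairing when testing destabilization, since
it carries energy in both engines' models.

**Destabilizers** (per stem of the optimal structure, size ≥ 2 by default;
single-pair stems are skippable noise unless `attack_size1_stems` is set):

* SUB at the innermost 5' position of the stem, replacing the base with its
  partner's own base — two identical bases can never pair canonically, so
  this always breaks the innermost pair and shortens the helix. The worked
  examples fix this rule: the published example candidates (deletion `U4`,
  substitution `G4C`) are exactly the innermost-5' attacks, and the
  partner-base choice reproduces `G4C` verbatim where an
  "alphabetically-first non-pairing base" rule would give `G4A`;
* DEL at the same position;
* INS of a non-pairing base in the middle of the 5' strand (floor of the
  run's midpoint) — exactly **one** insertion candidate per optimal stem,
  because one bulge suffices to destabilize a helix while allowing several
  would blow up the set combinatorics.

Candidates produced independently by both derivations merge with role
`BOTH`. Open interpretation points, resolved as follows: gap deletions are
generated at *all* gap positions (both sides of two-sided loops);
destabilizing SUB/DEL attack the 5' strand only (one attack per helix per
type, mirroring the one-insertion rule; the worked examples show only
5'-side attacks).

## Set assembly, validation, ranking

N output slots are split over the k representatives as floor(N/k) each,
remainder one-each to the most distant representatives (they are the
priority of the whole construction). Per representative, an exact
combination recursion enumerates M-subsets of its candidate pool with
pairwise-distinct positions; the candidate order is reshuffled at every
recursion level (mutation types first, then candidates within type) by a
single seeded RNG, so truncation at the quota yields a type-diverse random
selection while subsets are never repeated. Sets never mix candidates from
different representatives. If a pool has fewer than M distinct positions it
contributes nothing (logged).

Every script is applied (edits processed in descending position order, so
wild-type coordinates never shift under mixed indels), the mutant refolded
with the run's engine, projected, and kept iff its projected distance from
the wild-type MFE structure is ≥ `validation_threshold` (default:
`dist1` — one notion of "deleterious" throughout, since "distant enough"
is otherwise unquantified). Identical scripts assembled from
different representatives are reported once. Survivors are sorted by
distance descending, ties by energy ascending then name; at most N are
returned. Identical (input, config, seed, engine version) runs are
byte-identical.

## Random-sequence experiment

`run_random_experiment` contrasts predictions with and without indel
support. Defaults — its study conditions — are 3 random uniform-i.i.d.
sequences of length 200 nt, M = 5, a target of ≥ 30 validated sets per
condition (the pipeline is asked for 60 per sequence and condition since
validation discards some), thermodynamic engine, `max_subopt` = 4000
sampled structures per run. Length 200 matches the reference experiment
this harness mirrors; the number of sequences and sets is scaled down to
desk scale. The
contrast is evaluated on the pooled per-set distance distributions
(two-sided Mann–Whitney U) and the pooled median |E_mutant − E_WT|.

At seed 0 this reproduces the published qualitative finding: the two
conditions' distance distributions are indistinguishable (p ≈ 0.06 > 0.05)
while substitution-only sets shift the refolded energy further (median
|ΔE| ≈ 3.2 vs ≈ 2.6 kcal/mol). The simple engine is deliberately *not*
used here: its integer pair-count energies barely move under 5 edits
(|ΔE| ≤ 2 for both conditions at these lengths), so the free-energy
contrast is inexpressible in that model — a fundamental granularity limit,
not a sampling artifact.

What the generator does *not* emulate: real functional RNAs are more
structured (lower MFE density) than uniform random sequences, and the
experiment says nothing about biological function, only about structure and
energy arithmetic. Passing it shows the pipeline's two conditions behave as
published on random inputs, not that predicted sets disrupt any particular
RNA in vivo.

## Hardness module

`MaxDelMutsInstance` carries (wild type, budget m, functional structure,
competing structures); the objective is E(mutant, functional) −
Σᵢ E(mutant, S̄ᵢ) under the unconstrained pair-counting model,
substitution-only (indels would re-index the structures). The reduction
from max-cut builds wt = Aⁿ, m = n, empty functional structure, and one
single-pair competing structure per edge — the simplest valid partition of
the edge set; a greedy matching partition is provided as an alternative
constructor, and tests verify the objective is invariant to the choice.
Brute-force solvers are guarded hard (C(n,m)·3^m ≤ 10⁶ scripts; 2ⁿ subsets
at n ≤ 20) and refuse larger instances explicitly rather than truncating.
Tie-breaking is enumeration order (positions lexicographic, bases
alphabetical). Tests verify, over random and cubic graphs, that the
brute-force optima of the two problems coincide and that the explicit
"cut side → G, rest → C" script attains the max-cut value.

## Numerical and interface conventions

* Coordinates are 1-based everywhere; insertion at position k places the
  new base immediately before wild-type position k (k = n+1 appends).
* Sequences are uppercased on read; T → U with a logged warning; any other
  character is rejected. Pipeline inputs are limited to 1000 nt.
* Energies print with 2 decimals; distances are integers.
* The CLI exits 0 when ≥ 1 set survives, 3 when none does, and fails with
  an actionable message when no suboptimal structure survives filtering
  (raise `e_range` or lower `dist1`).
* Problem sizes in the default test run: the benchmark reproduction
  consumes the full ~356k-structure ensemble (~5 s); the experiment uses
  3×2 pipeline runs at n = 200 (~15 s); brute-force equivalences use 50
  random graphs with n ≤ 8 plus the cubic graphs on 4 and 6 vertices.

## Known limitations

* No pseudoknots, tertiary interactions, or tree-edit/Hamming-on-sequence
  distances (possible extensions).
* The thermodynamic results are parameter-version-pinned; a different
  ViennaRNA release may shift representative structures and counts.
* Exhaustive deleterious-set enumeration is out of scope by design — the
  method's point is to produce a bounded, diverse sample quickly.
* k-medoids clustering of the ensemble (a cleaner notion of "one
  representative per cluster") is noted as future work, not implemented.
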