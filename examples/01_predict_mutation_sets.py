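"""Predict deleterious 4-point mutation sets for the 93-nt benchmark RNA.

Runs the complete pipeline — MFE fold, suboptimal ensemble, diversity
filtering, candidate discovery, randomized set assembly, refolding
validation — with the thermodynamic engine and prints the top-ranked sets.
Each row gives the set name (wild-type coordinates; "G4C" substitution,
"U4" deletion, "15A" insertion), the mutant's refolded free energy in
kcal/mol, and its structural distance from the wild-type MFE structure
(higher = more deleterious).
"""

from rnadel import MutationKind, RunConfig, fixtures, run_pipeline

cfg = RunConfig(
    sequence=fixtures.ARTIFICIAL_SEQUENCE,
    dist1=30, dist2=30, e_range=15,
    m=4, n_results=100,
    allowed=frozenset(MutationKind),
    seed=1,
    engine="thermodynamic",
)
result = run_pipeline(cfg)

print(f"wild type MFE: {result.wt_fold.energy:.2f} kcal/mol")
print(f"suboptimal representatives after filtering: {len(result.representatives)}")
print(f"validated mutation sets: {len(result.records)}")
print()
print("name\tenergy\tdistance")
for rec in result.records[:10]:
    print(f"{rec.name}\t{rec.energy:.2f}\t{rec.distance}")
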