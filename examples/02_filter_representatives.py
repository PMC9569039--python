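"""Reduce a huge suboptimal ensemble to a handful of diverse representatives.

The 93-nt benchmark has ~356,000 structures within 15 kcal/mol of its MFE.
The two-stage filter first drops everything within distance 30 of the
optimal structure, then greedily keeps structures mutually more than 30
apart, scanning from the most distant.  Six representatives survive; each
line shows its distance from the optimal structure and its free energy.
"""

from rnadel import FilterParams, ViennaEngine, filter_suboptimals, fixtures

engine = ViennaEngine()
seq = fixtures.ARTIFICIAL_SEQUENCE
wt = engine.fold_mfe(seq)
print(f"opt  {wt.dot_bracket}  {wt.energy:.2f}")

reps = filter_suboptimals(
    wt, engine.subopt(seq, 15), FilterParams(dist1=30, dist2=30)
)
for idx, rep in enumerate(reps, 1):
    print(f"sub{idx} {rep.fold.dot_bracket}  {rep.fold.energy:.2f}  d={rep.distance}")
print(f"\n{len(reps)} representatives (engine: {engine.version})")
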