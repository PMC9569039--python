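"""Derive "good" single-point mutations from a structure pair.

Uses the two bundled worked examples.  In the first, deleting loop
nucleotides U4 and U6 merges helices of the suboptimal structure (U4 also
shortens the optimal structure's only stem, hence role BOTH).  In the
second, substitution G4C zips two suboptimal stems together while breaking
the optimal helix's innermost pair, and insertion 15A adds a complementary
base on the narrow side of an asymmetric interior loop.
"""

from rnadel import MutationKind, collect_candidates, parse_dot_bracket
from rnadel.fixtures import EXAMPLE_DELETIONS, EXAMPLE_INDELS
from rnadel.structures import format_mutation_name

for title, ex, allowed in (
    ("deletions only", EXAMPLE_DELETIONS, {MutationKind.DEL}),
    ("substitutions + insertions", EXAMPLE_INDELS,
     {MutationKind.SUB, MutationKind.INS}),
):
    print(f"== {title} ==")
    print(f"seq {ex.sequence}")
    print(f"opt {ex.opt}")
    print(f"sub {ex.sub}")
    cands = collect_candidates(
        ex.sequence, parse_dot_bracket(ex.opt), parse_dot_bracket(ex.sub), allowed
    )
    for c in cands:
        print(f"  {format_mutation_name(c.mutation):>5}  {c.role.value:15}  {c.source}")
    print()
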