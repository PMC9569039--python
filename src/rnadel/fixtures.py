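"""Bundled reference fixtures used by worked examples and acceptance checks.

All strings are byte-exact copies of the published reference material this
package reproduces: a 93-nt artificial benchmark sequence with its optimal
structure and the six suboptimal representatives surviving the diversity
filter (thresholds 30/30, energy band 15 kcal/mol), plus two small worked
examples (a deletion-only one and an insertion/substitution one) and a toy
hairpin sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

#: 93-nt artificial benchmark sequence (printed as two lines, concatenated).
ARTIFICIAL_SEQUENCE = (
    "CCGGAAGAGGGGGACAACCCGGGGAAACUCGGGCUAAUCCCCCAUGU"
    "GGACCCGCCCCUUGGGGUGUGUCCAAAGGGCUUUGCCCGCUUCCGG"
)

ARTIFICIAL_OPT = (
    "(((((((.((((((...((((((....))))))....))))))..."
    "(((((.(((((....))))).)))))..((((...)))).)))))))"
)

#: The six reference suboptimal representatives, most distant first.
ARTIFICIAL_SUBOPT = (
    ".........(((.....)))..((((...(((((.((..(((....(((((.(((((....))))).)))))..)))..))))))).))))..",
    "(((((((.((((((((((((((((.....(((((((..........))).))))))))...)))).)))))...........))).)))))))",
    "(((((((.(((.((......(((...((..(((.......)))..))...)))((((.(((((.....))))).)))).)).))).)))))))",
    "(((((..((.(((.(((((((((....))))))......((......))....((((.(((((.....))))).)))).)))))).)))))))",
    ".((((((.(((.((...((((((....))))))...((.(((((...((.....))...))))).))((((...)))).)).))).)))))).",
    "........((((((...((((((....))))))....))))))..((((....((((.(((((.....))))).)))).....))))......",
)

#: Reference distances of the six representatives from the optimal structure
#: (positionwise dot-bracket distance).
ARTIFICIAL_DISTANCES = (43, 39, 39, 36, 35, 34)

#: Filter parameters under which the six representatives were selected.
ARTIFICIAL_DIST1 = 30
ARTIFICIAL_DIST2 = 30
ARTIFICIAL_E_RANGE = 15


@dataclass(frozen=True)
class WorkedExample:
    sequence: str
    opt: str
    sub: str
    set_name: str
    mutant_sequence: str
    mutant_opt: str
    mutant_sub: str


#: Deletion-only worked example: the two deletions U4-U6 merge the stems of
#: the suboptimal structure, making it outfold the original optimal one.
EXAMPLE_DELETIONS = WorkedExample(
    sequence="GAGUGUCGACUCCGCC",
    opt="((((....))))....",
    sub="..(.(.((....))))",
    set_name="U4-U6",
    mutant_sequence="GAGGCGACUCCGCC",
    mutant_opt="(((....)))....",
    mutant_sub="..((((....))))",
)

#: Insertion/substitution worked example: G4C zips two stems of the
#: suboptimal structure (and shortens the optimal stem); 15A inserts on the
#: narrow side of an asymmetric loop.
EXAMPLE_INDELS = WorkedExample(
    sequence="GAGGGUCGCCUCCGCGC",
    opt="((((....)))).....",
    sub="..(.(.((....))).)",
    set_name="G4C-15A",
    mutant_sequence="GAGCGUCGCCUCCGACGC",
    mutant_opt="(((......)))......",
    mutant_sub="..((((((....))))))",
)

#: Toy hairpin used in small demonstrations.  The 11-nt form appears in the
#: main description; a 10-nt variant ("GGGGAAACCC") appears in some figure
#: captions of the same source — both are kept, neither is used for
#: acceptance checks.
TOY_SEQUENCE = "GGGGAAACCCC"
TOY_SEQUENCE_SHORT = "GGGGAAACCC"
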