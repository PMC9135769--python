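"""Enumerate, rank and splice de novo junction loops.

Walks the loop-design stage: exhaustive sequence enumeration over the
restricted loop-propensity alphabets (9^3 = 729 three-residue and
8^4 = 4096 four-residue sequences), ranking by a conformational-homogeneity
score, top-50 selection per junction, and the 50^2 = 2500 Cartesian splice
set. Here the score is a cheap stand-in (scores normally come from scoring
a per-candidate conformational ensemble); the selection logic is identical.
"""

from topofold import (
    LoopCandidate,
    enumerate_loop_sequences,
    loop_alphabet,
    score_candidates,
    select_top_k,
    splice_combinations,
)

seq3 = enumerate_loop_sequences(loop_alphabet(3))
seq4 = enumerate_loop_sequences(loop_alphabet(4))
print(f"3-residue loops: {len(seq3)} sequences over {loop_alphabet(3).residues}")
print(f"4-residue loops: {len(seq4)} sequences over {loop_alphabet(4).residues}")

# Stand-in score: glycine/proline content as a crude flexibility proxy;
# real use scores each candidate's ensemble with conformational_homogeneity.
def flexibility(c: LoopCandidate) -> float:
    return 1.0 - (c.sequence.count("G") + c.sequence.count("P")) / len(c.sequence)

junction1 = score_candidates([LoopCandidate("C'-A'", s) for s in seq3], flexibility)
junction2 = score_candidates([LoopCandidate("A'-D'", s) for s in seq4], flexibility)

top1 = select_top_k(junction1, 50)
top2 = select_top_k(junction2, 50)
print(f"top-50 per junction; best J1 candidates: "
      f"{[c.sequence for c in top1[:3]]} (score {top1[0].score:.2f})")

spliced = splice_combinations(top1, top2)
print(f"spliced two-loop models: {len(spliced)} (= 50 x 50)")
# Lower scores mean more conformationally stable loops; the spliced pairs
# are the candidate set a full design round would re-evaluate jointly.
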