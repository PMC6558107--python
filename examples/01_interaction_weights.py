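"""Directed interaction weights from a tiny pair-growth table.

Each unordered organism pair yields two directed log2 weights,
w(i<-j) = log2(paired_i / single_i): the growth change of i caused by
co-culture with j.  Positive = promotion, negative = inhibition, and an
extinct co-culture (paired rate 0) is clamped to the floor and flagged.
"""

from gutnet import PairGrowthRecord, build_interaction_matrix

records = [
    # b doubles a's growth; a halves b's growth
    PairGrowthRecord("Faecalibacterium_prausnitzii", "Bacteroides_fragilis",
                     "western", 0.40, 0.20, 0.80, 0.10),
    # c drives a extinct; a leaves c unchanged
    PairGrowthRecord("Faecalibacterium_prausnitzii", "Escherichia_coli",
                     "western", 0.40, 0.30, 0.00, 0.30),
]

matrix = build_interaction_matrix(records, diet="western")
print(f"{len(matrix)} directed weights from {len(records)} pairs:")
for (target, source), w in sorted(matrix.items()):
    flag = "  [clamped]" if matrix.is_clamped(target, source) else ""
    print(f"  w({target} <- {source}) = {w:+.2f}{flag}")
print()
print("A weight of +1 means the partner doubles the target's growth rate;")
print("-10 is the clamp floor recording extinction in co-culture.")
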