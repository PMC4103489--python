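"""Compare the three gene-set similarity coefficients.

Overlap rewards containment, Jaccard penalizes size differences, and the
combined coefficient blends the two with a constant k.
"""

from enrichmap import combined, jaccard, overlap

a = {"TBX20", "GATA4", "NKX2-5", "MEF2C"}
b = {"GATA4", "NKX2-5", "HAND2"}
small = {"TBX20", "GATA4"}

print(f"jaccard(a,b)  = {jaccard(a, b):.4f}   # 2 shared / 5 in the union")
print(f"overlap(a,b)  = {overlap(a, b):.4f}   # 2 shared / 3 in the smaller set")
for k in (0.0, 0.5, 1.0):
    print(f"combined(a,b,k={k}) = {combined(a, b, k):.4f}")
print(f"overlap(small,a) = {overlap(small, a):.1f}  # containment maxes overlap")
print(f"jaccard(small,a) = {jaccard(small, a):.1f}  # but not jaccard")
# For any pair, jaccard <= combined <= overlap: the combined coefficient
# interpolates between them, so the edge filter behaves predictably when
# switching metrics.
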