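"""Connectivity length of the six published end-state compositions.

L_c = sum_i sqrt(N_i) over the complexes of a frame; smaller values mean
stronger aggregation.  The values printed here are the study's Table-2
column, recomputed from the complex compositions.
"""

from zincagg import connectivity_length
from zincagg.presets import REPORTED_COMPOSITIONS

print(f"{'system':<10}{'t/ns':>6}  {'composition':<22}{'L_c':>6}")
for (name, t), comp in sorted(REPORTED_COMPOSITIONS.items()):
    if name.endswith("_premerge"):
        continue
    sizes = "+".join(str(s) for s in comp.sizes)
    print(f"{name:<10}{t:>6}  {sizes:<22}{round(connectivity_length(comp), 2):>6}")

pre = REPORTED_COMPOSITIONS[("system2_premerge", 100)]
post = REPORTED_COMPOSITIONS[("system2", 100)]
print(
    f"\nProximity merge (system2, 100 ns): {pre.sizes} -> {post.sizes}, "
    f"L_c {round(connectivity_length(pre), 2)} -> "
    f"{round(connectivity_length(post), 2)}"
)
print("The dimer-seeded system (system2) aggregates far more strongly than")
print("the zinc-saturated monomer system (system1): 6.15 vs 11.91 at 100 ns.")
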