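"""Coarse-grained Brownian aggregation of the 19-dimer system.

Builds the 19-dimer preset (15 nm periodic box, 2.4 nm minimum initial
separation), runs the sticky-sphere Brownian simulator for 100 ns of
model time, and tracks the connectivity length of the detected complex
composition frame by frame.  L_c starts at 19 (all units free) and
decreases monotonically as irreversible zinc-bridge-like bonds form.
"""

from zincagg import build_system, composition_timeseries, lc_timeseries, simulate
from zincagg.presets import SYSTEM_PRESETS

params = SYSTEM_PRESETS["system2"].sim_params(seed=7, n_steps=1000)
topology, frame, layout = build_system(params)
trajectory = simulate(topology, frame, params, layout)

series = composition_timeseries(trajectory, cutoff=0.45, merge_cutoff=1.0)
lcs = lc_timeseries(series)

print(f"{'t/ns':>6} {'L_c':>7}  composition")
for f, comp, lc in list(zip(trajectory.frames, series, lcs))[::10]:
    sizes = "+".join(str(s) for s in comp.sizes)
    print(f"{f.time / 1000:>6.0f} {lc:>7.2f}  {sizes}")

final = series[-1]
print(f"\nAfter {trajectory.frames[-1].time / 1000:.0f} ns the {final.n_units} "
      f"dimer units form {final.n_complexes} complexes (largest "
      f"{max(final.sizes)}); L_c fell from 19.00 to {lcs[-1]:.2f}.")
print("Lower L_c = stronger aggregation; a single 19-unit complex would give 4.36.")
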