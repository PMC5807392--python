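"""The jump-up region: where in the slow plane a stimulus triggers a spike.

Membrane potential and the potassium gate are fast; [Ca] and E_net drift
slowly. Freezing the fast variables at their rest values and probing a grid
of slow-variable combinations with a single pulse carves the plane into a
firing ("jump-up") region and a silent region. Habituation is the slow
trajectory drifting out of the jump-up region; irregular responding happens
when it hovers near the boundary.
"""

import numpy as np

from mauthner import ModelParameters, jump_up_grid, run_habituation_protocol, slow_projection

params = ModelParameters.for_phenotype("dominant")
grid = jump_up_grid(params, increment=0.02)

print("fired grid (rows: [Ca] 3.0 -> 3.2, cols: E_net 0.9 -> 1.2):")
for j, ca in enumerate(grid.Ca):
    row = "".join("#" if f else "." for f in grid.fired[j])
    print(f"  [Ca]={ca:.2f}  {row}")
print(f"\nboundary E_net per [Ca]: {np.array2string(grid.boundary, precision=2)}")

trace, series = run_habituation_protocol(params, frequency=1.0, count=40)
proj = slow_projection(trace, trace.train, series)
inside = [grid.in_jump_up_region(ca, e) for ca, e in zip(proj.Ca, proj.E_net)]
print(f"\ndominant-like 1 Hz trajectory: starts inside = {inside[0]}, "
      f"stimuli spent inside = {sum(inside)} of {len(inside)}")
print("The trajectory exits the jump-up region after the first response and")
print("stays out - that exit is the habituation mechanism.")
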