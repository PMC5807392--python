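"""Rest states of the M-cell model for the three social phenotypes.

The maximal net excitation ag_max stands in for social status: each phenotype
relaxes, without stimulation, to a slightly different quasi-steady state of
membrane potential v, potassium gate n, intracellular calcium [Ca] and
adaptation E_net. These states seed every stimulation protocol.
"""

from mauthner import ModelParameters, quasi_steady_state

for phenotype in ("dominant", "communal", "subordinate"):
    params = ModelParameters.for_phenotype(phenotype)
    state = quasi_steady_state(params)
    c = state.cell1
    print(f"{phenotype:>12} (ag_max={params.ag_max}): "
          f"v={c.v:8.4f} mV  n={c.n:.6f}  [Ca]={c.Ca:.4f}  E_net={c.E_net:.4f}")

print()
print("The cell rests around -34.3 mV; more excitable phenotypes (higher")
print("ag_max) carry a slightly higher adaptation level E_net, which is what")
print("lets them keep answering repeated stimuli longer.")
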