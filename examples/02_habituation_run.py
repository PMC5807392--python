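"""Habituation of the startle response under 1 Hz and 0.2 Hz pulse trains.

Forty depolarizing pulses are delivered to cell 1 from its quasi-steady
state. At 1 Hz the dominant-like model answers only the first stimulus and
then falls silent (strong habituation); the subordinate-like model keeps
answering intermittently. At 0.2 Hz the inter-stimulus recovery is long
enough that every phenotype responds to nearly every pulse.
"""

from mauthner import ModelParameters, faithfulness, run_habituation_protocol

for freq in (1.0, 0.2):
    print(f"--- {freq} Hz, 40 stimuli ---")
    for phenotype in ("dominant", "communal", "subordinate"):
        params = ModelParameters.for_phenotype(phenotype)
        trace, series = run_habituation_protocol(params, frequency=freq, count=40)
        pattern = "".join("|" if f else "." for f in series.fired)
        frac = faithfulness(series, 20000.0, series.stimulus_times[-1] + 1.0)
        print(f"{phenotype:>12}: {pattern}  response rate {frac:.2f}")
    print()

print("Each '|' is an escape spike, '.' a skipped stimulus. The response")
print("rate is the Faithfulness statistic over the whole train.")
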