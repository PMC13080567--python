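"""One-way sensitivity analysis: which inputs move the ICER the most?

Each parameter is pushed to the ends of its plausible range with everything
else at base, and the resulting ICER excursion is ranked (tornado order).
"""

from dkdcea import default_inputs, evaluate
from dkdcea.sensitivity import owsa, tornado_frame

inputs = default_inputs()
entries = owsa(inputs)
print(f"base-case ICER: {evaluate(inputs).icer:,.0f} USD/QALY\n")
print(tornado_frame(entries).head(10).to_string(index=False,
      float_format=lambda v: f"{v:,.1f}"))
print()
print("'spread' is |ICER(high) - ICER(low)|: the wider the bar, the more the")
print("cost-effectiveness conclusion depends on that input. Test performance")
print("(especially the AI assay's specificity) dominates.")
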