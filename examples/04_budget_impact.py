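"""Budget impact of adopting the assay for 42,000 tested patients.

Undiscounted annual cost differences (assay arm minus standard of care),
scaled to the tested population, for a one-time testing wave and for a
recurring program testing the same number of new patients every year.
"""

from dkdcea import default_inputs
from dkdcea.budget import bia_one_time, bia_recurring

inputs = default_inputs()
one = bia_one_time(inputs, 42_000)
rec = bia_recurring(inputs, 42_000)

print("year   one-time ($M)   recurring ($M)")
for y, (a, b) in enumerate(zip(one.annual, rec.annual), start=1):
    print(f"  {y}        {a/1e6:8.2f}        {b/1e6:8.2f}")
print(f"total     {one.cumulative/1e6:8.2f}        {rec.cumulative/1e6:8.2f}")
print(f"share of a $70B/year budget over 5 years: "
      f"{one.budget_share:.4%} (one-time), {rec.budget_share:.4%} (recurring)")
print()
print("Year 1 of the one-time wave carries the $1,050 assay fee for every")
print("tested patient; later years reflect downstream care-cost differences.")
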