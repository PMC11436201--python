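"""Serial dilution planning and dietary intake arithmetic.

Chemicals are prepared as 1000x stocks in 100% DMSO, diluted 1:100 to a
10x working solution in 1% DMSO, and 30 uL is added to each 300 uL well
for a nominal 1x dose in 0.1% DMSO. Intake assumes a fly consumes
~1.5 uL of food and water per day.
"""

from ovicount import MOLECULAR_WEIGHTS, intake_ng_per_day, plan_dilution, round_intake

plan = plan_dilution()
for step in plan.steps:
    print(f"{step.name:>8}: {step.fold_concentration:8.3f}x chemical, "
          f"{step.dmso_percent:6.3f}% DMSO  [{step.convention}]")
print("note: nominal treats 30 uL into 300 uL as a 10-fold step; the exact "
      "volumetric factor is 30/330 = 10/11 of nominal\n")

for chem, conc in (("rapamycin", 25.0), ("rapamycin", 0.1), ("bendiocarb", 0.1)):
    est = intake_ng_per_day(conc, MOLECULAR_WEIGHTS[chem], consumption_uL=1.5)
    print(f"{chem:>10} at {conc:>5} uM -> {round_intake(est.ng_per_day)} ng/day")
# The ng/day numbers are what a fly actually ingests at each media dose.
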