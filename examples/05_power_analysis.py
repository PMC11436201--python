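"""Downsampling power analysis: how many wells per condition suffice?

Repeatedly subsample k wells from each of two conditions, re-run the
t-test, and record the fraction of subsets that stay significant. The
fraction rises with k, showing the replicate count needed to keep
detecting a fixed effect.
"""

from ovicount import SyntheticCountModel, downsample_power, simulate_counts

model = SyntheticCountModel({"dmso": 36.0, "dosed": 18.0})  # a halving of fecundity
_, counts = simulate_counts(model, n_wells=60, seed=21)
control = counts.loc[counts["condition"] == "dmso", "count"].to_numpy()
dosed = counts.loc[counts["condition"] == "dosed", "count"].to_numpy()

print("subset size k -> fraction of 100 subsets with p < 0.05")
for k in (4, 8, 16, 24):
    res = downsample_power(control, dosed, k=k, n_iter=100, seed=k)
    print(f"  k={k:>2}: {res.fraction_significant:.2f}")
# With ~16 wells per condition nearly every subset reproduces the
# conclusion drawn from all 60 wells.
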