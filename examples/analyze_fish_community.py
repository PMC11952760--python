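"""Full conformity workup of one dataset: the EWH stream-fish biomass case.

Loads the 141 packaged relative-weight measurements (kg/km), tallies
first significant digits, computes every conformity statistic against
the Benford reference, classifies each, and attaches a bootstrap CI to
the two n-free descriptive statistics.
"""

import benfordeco as b

fish = b.load_case("fish_ewh")
diag = b.diagnostics(fish.raw_values)
print(f"n = {diag.n} measurements spanning {diag.orders_of_magnitude} orders of magnitude,")
print(f"all {diag.digits_populated} digit categories populated, "
      f"within the 80-500 inference window: {diag.morrow_valid}\n")

report = b.conformity_report(b.tally_digits(fish.raw_values))
for key, value in report.display().items():
    print(f"  {key:>15}: {value}")

assessment = b.classify(report)
print("\nPer-method verdicts:")
for v in assessment.verdicts:
    print(f"  {v.method:>8}: {v.state.value:<17} (statistic = {v.statistic:.3f}) {v.note}")
print(f"Overall: {assessment.overall.value}")

for stat in ("ssd", "cohen_w"):
    ci = b.bootstrap_ci(fish.tally, stat, B=1000, seed=1)
    print(f"\n95% bootstrap CI for {stat}: [{ci.lower:.3g}, {ci.upper:.3g}] "
          f"(sd of {ci.B} digit-resampled replicates = {ci.sd_boot:.3g})")

# d*_n = 0.638 is far below the 1.33 rejection value, SSD = 28.9 sits just
# above the <=25 strong-conformity band, Cohen-W = 0.182 is a weak effect,
# and no |Pearson residual| reaches 1.96: the community's biomass digit
# pattern is consistent with steady-state dynamic equilibrium.
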