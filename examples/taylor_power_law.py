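"""Power-law structure: Benford probabilities and Taylor mean-variance scaling.

The nine Benford probabilities fall off almost exactly as a power law of
the digit. Partitioning the raw fish biomass measurements by first digit
and regressing log variance on log mean recovers Taylor's power law
V = a * M^b with an exponent near 2 — an aggregated spatial pattern.
"""

import benfordeco as b

fit = b.loglog_power_fit(b.DIGITS, b.BENFORD_PROBS)
print(f"Benford probabilities vs digit: P(d) ~ {fit.coefficient:.3f} * d^{fit.exponent:.3f}, "
      f"R^2(log-log) = {fit.r_squared_loglog:.3f}")

fish = b.load_case("fish_ewh")
parts = b.digit_partition_stats(fish.raw_values)
print("\ndigit  count  mean     variance")
for d, members in sorted(parts.members.items()):
    v = parts.variances[d]
    print(f"  {d}    {len(members):3d}   {parts.means[d]:8.2f} {v:10.1f}")

x, y = parts.taylor_xy()
taylor = b.loglog_power_fit(x, y)
print(f"\nTaylor's law: V = {taylor.coefficient:.2f} * M^{taylor.exponent:.2f} "
      f"(r in log-log space = {taylor.r_loglog:.3f}, {taylor.n_points} digit classes)")
print("Exponent ~2 indicates strongly aggregated biomass across digit classes.")
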