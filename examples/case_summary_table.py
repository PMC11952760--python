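"""Regenerate the seven-case summary table and its cross-test agreement.

One row per case study with every conformity statistic, bootstrap CIs
for the two descriptive measures, and threshold flags; then Kendall's
tau between the inferential distance d*_n and each descriptive
statistic, showing the methods rank the cases almost identically.
"""

import benfordeco as b

names = [
    "succession_early", "succession_late",
    "diatoms_small", "diatoms_large",
    "salamanders_pre1990", "salamanders_post1990",
    "fish_ewh",
]
fixtures = {n: b.load_case(n) for n in names}
reports = {n: b.conformity_report(f.tally) for n, f in fixtures.items()}
oms = {n: f.expected.get("om") for n, f in fixtures.items()}
cis = {
    n: {
        "ssd": b.bootstrap_ci(f.tally, "ssd", B=1000, seed=2),
        "cohen_w": b.bootstrap_ci(f.tally, "cohen_w", B=1000, seed=2),
    }
    for n, f in fixtures.items()
}

table = b.summarize_cases(reports, diagnostics=oms, cis=cis)
print(table.to_string())

ds = [reports[n].morrow_d for n in names]
tau_ssd = b.kendall_tau(ds, [reports[n].ssd for n in names])
tau_w = b.kendall_tau(ds, [reports[n].cohen_w for n in names])
print(f"\nKendall tau, d*_n vs SSD: {tau_ssd:.3f}; d*_n vs Cohen-W: {tau_w:.3f}")
print("High rank agreement: the descriptive and inferential statistics order")
print("the seven cases almost identically, supporting a weight-of-evidence read.")
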