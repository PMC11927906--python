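"""Compare two paired classifiers with McNemar's chi-squared test.

On 180 paired predictions, suppose the ensemble alone got 32 items right
that the best single model missed (a = 32), and the best model alone got 1
(b = 1).  Only the discordant counts enter the statistic
(a - b)^2 / (a + b) on 1 df; the continuity-corrected variant uses
(|a - b| - 1)^2 / (a + b).
"""

from platescreen import build_agreement_table, mcnemar

for cc in (False, True):
    r = mcnemar(32, 1, continuity=cc)
    kind = "continuity-corrected" if cc else "uncorrected        "
    print(f"{kind}  chi2 = {r.statistic:6.2f}   p = {r.p_value:.2e}")

# building the table from raw label vectors
true = [1, 1, 1, 0, 0, 0, 1, 0]
ens = [1, 1, 1, 0, 0, 0, 1, 1]   # one extra miss
best = [1, 0, 1, 0, 1, 0, 1, 1]  # two extra misses
tab = build_agreement_table(true, ens, best)
print(f"\nagreement cells: both-correct {tab.both_correct}, ensemble-only "
      f"{tab.a_only}, best-only {tab.b_only}, both-wrong {tab.both_wrong}")
print("With a + b this small the asymptotic chi-squared test is unreliable; "
      "the printed 32/1 case is comfortably significant either way.")
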