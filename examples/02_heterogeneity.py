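"""Between-study variance: four point estimators and four 95% intervals.

Estimates tau2 for a small meta-analysis by DerSimonian-Laird (DL),
Jackson (J), Mandel-Paule (MP) and REML, with the Q-profile (QP),
Biggerstaff-Jackson (BJ), generalized-Q (J) and profile-likelihood (PL)
confidence intervals.  The four point estimates can differ by a factor
of two on the same data — that spread, not any single number, is the
message.
"""

from lrrmeta import MetaDataset, estimate_tau2, tau2_interval

# effects and within-study variances of 8 studies
data = MetaDataset.from_arrays(
    lrr=[0.85, -0.21, 0.31, 1.05, 0.02, 0.71, -0.30, 0.38],
    var=[0.04, 0.09, 0.02, 0.12, 0.03, 0.15, 0.05, 0.07],
)

print("point estimates of tau2:")
for method in ("DL", "J", "MP", "REML"):
    fit = estimate_tau2(data, method)
    note = " (truncated at 0)" if fit.truncated else ""
    print(f"  {method:5s} {fit.tau2:.4f}{note}")

print("\n95% intervals for tau2:")
for method in ("QP", "BJ", "J", "PL"):
    ci = tau2_interval(data, method)
    print(f"  {method:3s} [{ci.lower:.4f}, {ci.upper:.4f}]")
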