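"""Monte-Carlo evaluation of tau2 estimators in one simulation cell.

Reproduces, at reduced scale, the large-sample normal-model cell where
inverse-variance-based moment estimators go badly wrong: with means one
standard deviation from zero (mu_C = 1), K = 5 studies of n = 1000 and
tau2 = 1, DerSimonian-Laird underestimates the between-study variance
by about a third while Mandel-Paule stays nearly unbiased.
"""

import numpy as np

from lrrmeta import SimulationConfig, evaluate_cell

cfg = SimulationConfig(
    "normal", lam=0.0, tau2=1.0, mu_c=1.0, k=5, n=1000, reps=2000
)
res = evaluate_cell(
    cfg,
    np.random.default_rng(42),
    tau2_methods=("DL", "J", "MP", "REML"),
    tau2_intervals=(),
    lambda_methods=(),
    lambda_intervals=(),
)
print(res[["method", "bias", "mse", "mc_se_bias"]].round(4).to_string(index=False))
print(
    "\nbias = mean(tau2_hat) - 1 over 2,000 replications; mc_se_bias is\n"
    "the Monte-Carlo standard error of that mean.  DL and J are strongly\n"
    "negatively biased in this cell; MP and REML are much closer to 0."
)
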