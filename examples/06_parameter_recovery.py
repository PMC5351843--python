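"""Parameter-recovery and selection-power experiment.

Monte-Carlo check of the whole pipeline at the study's scale: 31 brood years,
residual sd 0.4, a moderately strong driver effect.  Reports bias, CI
coverage, and how often each candidate wins model selection.
"""

import prodshift as ps

cfg = ps.SimConfig(
    populations=[ps.PopulationParams("pws", sigma=0.4)], c_true=-0.5, seed=123
)
results = ps.recovery_experiment(cfg, n_reps=100)
summary = ps.summarize_recovery(results, cfg)
print(summary.round(4).to_string(index=False))
print(
    "\nCoverage near 0.95 and small bias mean the estimator and its\n"
    "uncertainty are trustworthy at this sample size; the selected_* rows\n"
    "show how often each candidate attained delta-AICc = 0."
)
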