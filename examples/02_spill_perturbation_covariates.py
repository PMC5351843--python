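"""Construct oil-spill perturbation covariates.

The 1989 spill can enter a productivity model as a pulse (one bad brood
year), a press (a permanent drop in mean productivity), or a pulse followed
by a linear 20-year recovery.  A lag of k shifts the affected brood year back
k years: a cohort spawned in 1987 entered the ocean as two-year-olds in 1989.
"""

import pandas as pd

import prodshift as ps

years = range(1981, 2012)
covs = {
    "pulse lag 0": ps.build_evos_covariate("pulse", 0, years),
    "press lag 0": ps.build_evos_covariate("press", 0, years),
    "recovery lag 0": ps.build_evos_covariate("pulse_recovery", 0, years),
    "pulse lag 2": ps.build_evos_covariate("pulse", 2, years),
}
frame = pd.DataFrame({k: c.data for k, c in covs.items()})
print(frame.loc[[1987, 1988, 1989, 1990, 1999, 2009]])
print(
    "\nEach column is one hypothesis about how the spill acted on brood-year\n"
    "productivity; the recovery shape halves by 1999 and reaches 0 by 2009."
)
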