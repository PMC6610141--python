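"""Selection into the sample and post-stratification re-weighting.

Participation is made more likely for the educated and less likely for
smokers (as observed for volunteer cohorts). Education-stratum weights
anchored to population proportions rebalance the selected sample.
"""

import dataclasses

import numpy as np
import pandas as pd

from edumr import SelectionModel, SimParams, selection_weights, simulate_cohort
from edumr.simulate import apply_selection

params = SimParams(
    n_individuals=80_000,
    selection_model=SelectionModel(intercept=0.0, coef_edu=0.4, coef_smoke=-1.0),
    seed=19,
)
cohort, _ = simulate_cohort(params)
selected, prob = apply_selection(cohort, params)

print(f"retained {selected.n}/{cohort.n} ({selected.n / cohort.n:.1%})")
print(f"mean education: full {cohort.edu_years.mean():.2f} y, selected {selected.edu_years.mean():.2f} y")
print(f"current smoking: full {cohort.smoke_current.mean():.1%}, selected {selected.smoke_current.mean():.1%}")

# stratify education as the census comparison does: left school before
# 16 / intermediate / degree-level (proxied by years >= 21)
def strata(c):
    s = pd.Series(
        pd.cut(
            c.edu_years, [-np.inf, 16, 21, np.inf],
            labels=["before_16", "intermediate", "degree"],
        )
    )
    return s.value_counts(normalize=True)

w = selection_weights(strata(selected), strata(cohort))
print("\nstratum weights (population/sample):")
print(w.round(3).to_string())
# Weighting the selected sample by these factors restores the full
# cohort's education distribution before re-estimating.
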