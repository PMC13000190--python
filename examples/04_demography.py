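"""Known-fate survival and the 16-stage matrix population model.

Estimates annual survival from synthetic fate records (overall and of
lead hazards only, with non-lead deaths censored), then assembles the
female-only projection matrix and reports the population growth rate.
"""

import numpy as np

from condorlead import (SimConfig, build_matrix, default_stage_structure,
                        generate_blood_samples, generate_dataset,
                        generate_fates, growth_rate, known_fate_fit,
                        rolling_survival)
import pandas as pd

cfg = SimConfig(n_individuals=30, year_span=(2002, 2011), seed=17)
data = generate_dataset(cfg)
samples, truth = generate_blood_samples(data)
fates = generate_fates(data, samples, truth)

overall = known_fate_fit(fates)
lead = known_fate_fit(fates, mode="lead")
print(f"{len(fates)} condor-years, "
      f"{(~fates['survived']).sum()} deaths")
print(f"S_Overall = {overall.survival:.3f} (SE {overall.survival_se:.3f})")
print(f"S_Pb      = {lead.survival:.3f} (non-lead deaths censored)\n")

annual = fates.groupby("Bioyear")["survived"].mean()
print("5-year rolling mean of annual survival:")
print(rolling_survival(annual).round(3).to_string(), "\n")

structure = default_stage_structure()
survival = {"FirstYear": 0.85, "Juvenile": 0.92, "YoungAdult": 0.94,
            "OlderAdult": 0.95, "Released": 0.88}
succ = {(h, b): p for h, p in (("NB", 0.35), ("FB", 0.55), ("SB", 0.25))
        for b in ("J", "YA", "OA")}
pm = build_matrix(structure, survival, succ)
lam, stable = growth_rate(pm)
print(f"16-stage matrix: population growth rate lambda = {lam:.3f}")
print("stable stage distribution (top 5):")
print(pd.Series(stable, index=pm.stage_names).sort_values(
    ascending=False).head().round(3).to_string())
print("""
lambda > 1 means growth; the condor system sits near or below 1, which is
why small survival gains from lower lead exposure matter so much.""")
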