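"""Generate a small synthetic lung-VMAT cohort and summarize it.

Builds 20 patients on a 16^3 grid: each has a planning-dose grid, organ
masks (homolateral/contralateral lung, heart, posterior Pmap sub-region),
clinical covariates, and planted APT2/APT3 outcomes whose risk rises with
the mean Pmap dose and the two-lung mean dose.
"""

import numpy as np

from aptox import CohortConfig, generate_cohort

config = CohortConfig(n_patients=20, grid_shape=(16, 16, 16), seed=7,
                      calibration_n=300)
cohort = generate_cohort(config)

print(f"patients: {len(cohort)}")
print(f"APT2 events: {sum(r.apt2 for r in cohort)} "
      f"(target marginal rate {config.target_event_rate:.1%})")
r = cohort[0]
lungs = r.structures.masks["lungs"].astype(bool)
pmap = r.structures.masks["pmap_region"].astype(bool)
print(f"first patient: peak dose {r.dose.values.max():.1f} Gy "
      f"(prescription {config.prescription_dose} Gy)")
print(f"  mean lung dose {r.dose.values[lungs].mean():.1f} Gy, "
      f"mean Pmap dose {r.dose.values[pmap].mean():.1f} Gy")
print(f"  covariates: {r.covariates}")
# Higher Pmap dose should mean more events on average:
doses = np.array([p.dose.values[p.structures.masks['pmap_region'] > 0].mean()
                  for p in cohort])
events = np.array([p.apt2 for p in cohort])
print(f"mean Pmap dose | event: {doses[events].mean():.1f} Gy, "
      f"| no event: {doses[~events].mean():.1f} Gy")
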