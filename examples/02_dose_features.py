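"""Extract dose-volume and texture features from a synthetic cohort.

Computes the feature table used by the prediction models: Vx/Dmean
dose-volume features per organ, the six co-occurrence/histogram texture
features of the dose map (1 Gy = 1 grey level), and encoded clinical
covariates.
"""

from aptox import CohortConfig, extract_feature_table, generate_cohort

config = CohortConfig(n_patients=10, grid_shape=(16, 16, 16), seed=3,
                      calibration_n=200)
table = extract_feature_table(generate_cohort(config))

shown = ["V5_LungH", "V30_2Lungs", "DMean_LungH", "DMean_2Lungs",
         "DMean_Pmap", "LungH_Variance", "LungH_Contrast", "LungH_Entropy",
         "Lungs_Energy", "apt2"]
print(table[shown].round(2).to_string())
print(f"\n(full table has {table.shape[1]} columns: dosimetric, radiomic, "
      "clinical, outcomes)")
print("V5_LungH is the % of the homolateral lung receiving >= 5 Gy;")
print("LungH_Contrast summarizes local dose heterogeneity in that lung;")
print("DMean_Pmap is the mean dose to the toxicity-sensitive sub-region.")
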