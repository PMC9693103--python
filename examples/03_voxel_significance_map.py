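"""Voxel-based significance mapping with a planted sensitive region.

80 registered dose maps share one frame; toxicity depends only on the
mean dose to a planted 5^3 sub-region. A per-voxel Welch t-test with
max-T permutation family-wise error control should light up exactly that
region; overlap with the truth is scored by the DICE coefficient.
"""

from aptox import (
    CohortConfig,
    VoxelStack,
    dice,
    extract_region,
    generate_planted_voxel_data,
    max_t_permutation,
)

config = CohortConfig(n_patients=2, grid_shape=(16, 16, 16))
data, lungs, labels, planted = generate_planted_voxel_data(
    config, n_patients=80, region_size=(5, 5, 5), effect=1.0, seed=5
)
stack = VoxelStack(data=data, valid_mask=lungs, labels=labels)
sig = max_t_permutation(stack, n_perm=500, seed=5, alpha=0.05)
region = extract_region(sig, alpha=0.05, min_cluster=2)

print(f"patients: {data.shape[0]} ({labels.sum()} with APT2)")
print(f"lung voxels analysed: {int(lungs.sum())}, planted: {int(planted.sum())}")
print(f"significant voxels at alpha=0.05 (FWE): {int(region.sum())}")
print(f"DICE(recovered, planted) = {dice(region, planted):.2f}")
print("DICE near 1 means the permutation map localized the sensitive "
      "region; the max-T correction keeps false positives off the rest "
      "of the lungs.")
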