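"""BOLD-correct a synthetic VASO nulled/not-nulled volume pair.

The nulled series carries the CBV-weighted columnar response multiplied by
shared BOLD contamination; dividing by the not-nulled series removes the
contamination.  With noise disabled the recovery is exact at time points
sampled by both acquisitions.
"""

import numpy as np

from lamodc import (AcquisitionModel, RunDesign, bold_correct, make_cortex_patch,
                    simulate_odc_pattern, simulate_vaso_pair)

patch = make_cortex_patch(32, 32)
cmap = simulate_odc_pattern(patch, seed=2)
design = RunDesign(tr_s=5.0)  # effective pair TR of 5 s -> 54 pairs per run

model = AcquisitionModel.vaso(noise_sigma_deep=0.0, noise_sigma_pial=0.0)
nulled, not_nulled, truth = simulate_vaso_pair(
    patch, cmap, design, model, seed=0, bold_amp=0.05,
    aligned_timestamps=True, return_truth=True)
print(f"nulled/not-nulled volumes per run: {nulled.n_volumes}/{not_nulled.n_volumes}")

corrected, valid = bold_correct(nulled, not_nulled, target_tr_s=3.0)
print(f"corrected series: {corrected.n_volumes} volumes at TR "
      f"{corrected.tr_s:.0f} s, {valid.mean():.0%} voxels valid")

aligned = corrected.timestamps_s % 15.0 == 0
src = np.isin(nulled.timestamps_s, corrected.timestamps_s[aligned])
err = corrected.values[..., aligned] - (1.0 - truth["cbv_nulled_times"][..., src])
print(f"max |corrected - (1 - cbv)| at aligned grid points: {np.abs(err).max():.2e} "
      "(BOLD contamination removed exactly)")
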