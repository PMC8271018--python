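"""Microstructural profile covariance from depth-wise intensity profiles.

Simulates 16-depth intensity profiles with block cytoarchitectonic
structure and an injected anterior-posterior (y) trend, removes the trend,
and computes MPC (partial correlation controlling the cortex-wide mean
profile, log-transformed on positive values).
"""

import numpy as np

import hubwire

profiles, y = hubwire.simulate_intensity_profiles(
    n_regions=60, n_surfaces=16, n_blocks=4, seed=5, noise_sd=0.3
)
resid = hubwire.residualize_profiles(profiles.drop(columns="block"), y)
trend = max(abs(np.corrcoef(resid[:, j], y)[0, 1]) for j in range(16))
print(f"max |residual-y correlation| across depths: {trend:.2e}")

mpc, raw_r = hubwire.mpc_matrix(resid)
blocks = profiles["block"].to_numpy()
iu, ju = np.triu_indices(60, k=1)
same = blocks[iu] == blocks[ju]
print(f"mean MPC within blocks:  {np.nanmean(mpc[iu[same], ju[same]]):+.3f}")
print(f"mean MPC between blocks: {np.nanmean(mpc[iu[~same], ju[~same]]):+.3f}")
print(
    "\nRegions sharing a depth-profile template (same cytoarchitectonic "
    "block) show systematically higher profile covariance."
)
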