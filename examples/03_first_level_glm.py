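"""Fit the first-level AR(1) GLS model on simulated voxel time series.

One run of 302 volumes (TR 3 s) is simulated from 18 planted block betas
with AR(1) noise, then refit with the two-pass prewhitening estimator
(OLS -> pooled residual lag-1 rho -> prewhiten -> OLS).  Two regimes are
shown: a long series with a small design, where rho-hat converges on the
planted value, and the full 56-column run design, where the drift and
block regressors absorb most of the slow noise so the pooled residual
rho-hat is much smaller — the GLS betas remain unbiased either way.
"""

import numpy as np
import pandas as pd

from lamfmri.design import build_run_design
from lamfmri.glm import DesignMatrix, fit_glm_ar1
from lamfmri.synth import simulate_voxel_timeseries

rng = np.random.default_rng(0)

# regime 1: plenty of residual degrees of freedom -> rho recovered
n = 1200
x = rng.normal(size=(n, 4))
df = pd.DataFrame({f"x{i}": x[:, i] for i in range(4)} | {"constant": np.ones(n)})
toy = DesignMatrix(matrix=df, frame_times=np.arange(n, dtype=float),
                   block_hrf_columns=[f"x{i}" for i in range(4)],
                   derivative_columns=[], event_columns=[], drift_columns=[],
                   nuisance_columns=[], degenerate_columns=[])
noise = np.empty(n)
noise[0] = rng.normal()
e = rng.normal(0.0, np.sqrt(1 - 0.4**2), size=n)
for t in range(1, n):
    noise[t] = 0.4 * noise[t - 1] + e[t]
fit_toy = fit_glm_ar1(x @ np.ones(4) + noise, toy)
print(f"long series (n=1200, 5 columns): rho-hat = {fit_toy.rho:.3f} "
      "(planted 0.4)")

# regime 2: the full run design (block + derivative + drift columns)
design = build_run_design(rng_seed=0)
true_betas = rng.normal(0.0, 1.0, size=18)
series, dm = simulate_voxel_timeseries(design, true_betas, run=1,
                                       ar1_rho=0.4, noise_sd=0.5, rng_seed=1)
fit = fit_glm_ar1(series, dm)
est = fit.block_betas(dm.block_hrf_columns)[:, 0]
print(f"full run design ({len(series)} volumes, {dm.matrix.shape[1]} columns: "
      f"{len(dm.block_hrf_columns)} block HRF + derivatives, "
      f"{len(dm.drift_columns)} cosine drift, events, constant):")
print(f"  residual rho-hat = {fit.rho:.3f} "
      "(drift/block columns absorb the slow noise)")
print(f"  block-beta recovery RMSE = "
      f"{np.sqrt(np.mean((est - true_betas) ** 2)):.3f} (noise sd 0.5)")

clean, _ = simulate_voxel_timeseries(design, true_betas, run=1)
fit0 = fit_glm_ar1(clean, dm)
err0 = np.abs(fit0.block_betas(dm.block_hrf_columns)[:, 0] - true_betas).max()
print(f"  noiseless recovery max |error| = {err0:.2e} (machine precision)")
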