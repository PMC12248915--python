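"""Simulate one voxel's hyperpolarized pyruvate/lactate dynamics and
invert them with the inputless two-site exchange fit.

The apparent conversion rate k_PL (reported in ks^-1 = 1e-3 s^-1) is the
imaging surrogate of LDH-driven Warburg metabolism. The fit uses the
measured pyruvate curve itself as the source term, so no arterial input
function is required; on noiseless data the recovery is exact.
"""

import numpy as np

from hpmfm import (
    AcquisitionConfig,
    DynamicSeries,
    KineticParams,
    fit_kpl_inputless,
    simulate_dynamics,
)

acq = AcquisitionConfig(tr_seconds=3.0, n_frames=20,
                        flip_pyr_degrees=15, flip_lac_degrees=30,
                        noise_sigma=0.0)
true_kpl_ks = 17.0  # ks^-1, the dichotomization cutoff regime

s_pyr, s_lac = simulate_dynamics(
    KineticParams(kpl_per_second=true_kpl_ks / 1000.0), acq
)
series = DynamicSeries(
    s_pyr.reshape(1, 1, 1, -1), s_lac.reshape(1, 1, 1, -1), acq, np.eye(4)
)
fitted = fit_kpl_inputless(series).ravel()[0]

print(f"pyruvate peak signal : {s_pyr.max():.4f} (arb. units)")
print(f"lactate  peak signal : {s_lac.max():.4f}")
print(f"true k_PL            : {true_kpl_ks:.3f} ks^-1")
print(f"fitted k_PL          : {fitted:.6f} ks^-1")
# The fitted value matches the ground truth to numerical precision
# because fitter and simulator share one discrete frame recursion.

# With measurement noise (peak SNR ~ 20) the per-voxel estimate scatters
# but stays nearly unbiased:
rng = np.random.default_rng(0)
noisy = AcquisitionConfig(noise_sigma=0.0074)
pairs = [simulate_dynamics(KineticParams(kpl_per_second=0.017), noisy, rng)
         for _ in range(100)]
sp = np.stack([a for a, _ in pairs]).reshape(100, 1, 1, -1)
sl = np.stack([b for _, b in pairs]).reshape(100, 1, 1, -1)
fits = fit_kpl_inputless(DynamicSeries(sp, sl, noisy, np.eye(4))).ravel()
print(f"noisy fits (n=100)   : mean {fits.mean():.2f} ks^-1, "
      f"SD {fits.std():.2f} (bias {100 * (fits.mean() - 17) / 17:+.2f}%)")
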