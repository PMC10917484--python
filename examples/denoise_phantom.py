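"""Denoise a synthetic filament stack and quantify the improvement.

Builds a small noisy phantom (Gaussian noise SD 0.1 on structures of unit
intensity), runs the optimized denoiser, and prints RMSE against the ground
truth before and after, plus the SNR gain in dB.  Lower RMSE / higher SNR
after denoising means noise was removed while the filaments survived.
"""

import numpy as np

from hessdenoise import DenoiseParams, PhantomSpec, denoise_optimized, make_phantom, quality

clean, noisy = make_phantom(
    PhantomSpec(shape=(64, 64, 32), gaussian_noise_sd=0.1, seed=12))

params = DenoiseParams(mu=10.0, sigma=1.0, iterations=40, precision="binary64")
result = denoise_optimized(noisy, params)


def rmse(a, b):
    return float(np.sqrt(np.mean((np.asarray(a, np.float64) - np.asarray(b, np.float64)) ** 2)))


print(f"RMSE vs clean, noisy input : {rmse(noisy.data, clean.data):.6f}")
print(f"RMSE vs clean, denoised    : {rmse(result.stack.data, clean.data):.6f}")
print(f"SNR of noisy input  : {quality(clean, noisy).snr_mean_db:.2f} dB")
print(f"SNR after denoising : {quality(clean, result.stack).snr_mean_db:.2f} dB")
print(f"iterations completed: {result.counters.iterations_completed}")
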