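"""How Rician noise affects the measured index.

Repeats the measurement on the same phantom under magnitude (Rician) noise
at several SNR levels and compares the replicate mean to the closed-form
truth.
"""

import numpy as np

import dwialps as d

rois = d.default_roi_set()
truth = d.closed_form_index(d.default_phantom_spec())
print(f"ground-truth index: {truth:g}   (50 noise replicates per SNR)")
print(f"{'SNR':>5} {'sigma':>6} {'mean':>8} {'SD':>7} {'bias %':>7}")

for snr in (50, 20, 10):
    sigma = 1000.0 / snr  # white-matter S0 is 1000
    spec = d.default_phantom_spec(noise_sigma=sigma)
    est = [
        d.measure_subject(d.generate_phantom(spec, seed=s)[0], rois).alps_index
        for s in range(50)
    ]
    bias = (np.mean(est) - truth) / truth * 100
    print(f"{snr:>5} {sigma:>6.0f} {np.mean(est):>8.4f} {np.std(est):>7.4f} "
          f"{bias:>+7.2f}")

print()
print("The replicate mean stays within a few percent of truth down to SNR 10;")
print("scatter (SD) grows as noise rises, which is why cohort studies average")
print("two observers and many subjects.")
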