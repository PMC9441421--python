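"""Measure the ALPS index on a simulated diffusion phantom, end to end.

Builds a noiseless tensor phantom (known ground truth), computes per-axis
ADC maps, measures the four fiber-area ROIs and prints the index.
"""

import dwialps as d

spec = d.default_phantom_spec()            # proj D=(1.2,0.4,1.4), assoc D=(1.2,1.4,0.4)
study, truth = d.generate_phantom(spec, seed=7)
rois = d.default_roi_set()

m = d.measure_subject(study, rois, observer_id="A")

print(f"ADCx projection area : {m.adcx_proj:.4f}  (1e-3 mm^2/s)")
print(f"ADCx association area: {m.adcx_assoc:.4f}")
print(f"ADCy projection area : {m.adcy_proj:.4f}")
print(f"ADCz association area: {m.adcz_assoc:.4f}")
print(f"ALPS index           : {m.alps_index:.6f}")
print(f"closed-form truth    : {truth['alps_index']:g}")
print()
print("The index is the ratio of diffusivity along the perivascular direction")
print("(x) to the fiber-perpendicular diffusivities (y in the projection area,")
print("z in the association area); on this noiseless phantom it matches the")
print("generating tensors' ratio exactly.")
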