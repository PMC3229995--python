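"""Simulate a phantom scan pair and measure its wear with the CT pipeline.

Generates a cup/head phantom with a known 0.5 mm wear vector along the
cup x-axis, repositions each scan by a random rigid motion (as the
physical phantom was moved in the scanner between acquisitions), and
recovers the wear from the labelled point clouds alone.
"""

import numpy as np

from cupwear import PhantomSpec, ct_wear, generate_scan_pair

spec = PhantomSpec(seed=42, noise_sigma=0.1, wear_vector_true=(0.5, 0.0, 0.0))
pre, post, truth = generate_scan_pair(spec)

result = ct_wear(pre, post, filter_threshold=0.5)

print(f"true linear wear      : {truth.linear_wear:.3f} mm "
      f"(theta {truth.theta:.0f} deg, phi {truth.phi:.0f} deg)")
print(f"measured linear wear  : {result.linear_wear:.3f} mm "
      f"(theta {result.theta:.0f} deg, phi {result.phi:.0f} deg)")
print(f"wear vector (cup frame): {np.round(result.wear_vector, 3)} mm")
head_fit = result.diagnostics["pre"]["head"]
print(f"pre-scan head sphere  : diameter {head_fit['diameter_mm']:.2f} mm, "
      f"{head_fit['n_rejected']} artifact points eliminated")

# The measured wear should sit within a few hundredths of a millimetre
# of the simulated truth; the angle errors reflect how well the cup
# opening faces pin down the in-plane reference direction.
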