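"""ISO-style repeatability from duplicate scans and gravimetric volume.

Simulates twelve cups each measured twice (the phantom was scanned in
two different positions) with a within-unit SD of 0.14 mm, estimates
the 95%-level repeatability, and converts a gravimetric mass loss to
wear volume at the cup material density.
"""

import numpy as np

from cupwear import repeatability_iso, wear_volume_from_mass

rng = np.random.default_rng(0)
true_wear = rng.normal(1.0, 0.5, size=12)  # per-cup true values, mm
duplicates = true_wear[:, None] + rng.normal(0.0, 0.14, size=(12, 2))

r = repeatability_iso(duplicates)
print(f"repeatability (95% level): {r:.2f} mm "
      f"(population value 1.96*sqrt(2)*0.14 = {1.96*np.sqrt(2)*0.14:.2f} mm)")

mass_loss_mg = 200.0  # the wear test ran until at least 200 mg was removed
volume = wear_volume_from_mass(mass_loss_mg)  # density 0.935 mg/mm^3
print(f"{mass_loss_mg:.0f} mg mass loss = {volume:.2f} mm^3 wear volume")

# Repeatability here is the largest absolute difference expected between
# two repeated measurements of the same cup in 95% of cases.
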