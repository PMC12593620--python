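"""Simulating a two-channel field and quantifying it back.

Renders one synthetic F740/F910 field of CA1 pyramidal somata with
photon noise, runs soma detection and ratio quantification, converts to
OxD, and compares the recovered values against the generator truth.
"""

import numpy as np

from redoxmap import DEFAULT_CALIBRATION, SimScenario, make_fluorophore_model, simulate_field
from redoxmap.calibration import oxd_from_ratio
from redoxmap.workflows import quantify_field

scenario = SimScenario(cells_per_field=12)
model = make_fluorophore_model(DEFAULT_CALIBRATION)
field, truth = simulate_field(
    scenario, model, region="CA1", genotype="WT", age_group="p50", seed=42
)
print(f"rendered {field.shape} field with {len(truth)} somata "
      f"(photon scale {scenario.photon_scale:g}, read noise {scenario.read_noise_sd})")

measurements = quantify_field(field)
print(f"detected {len(measurements)} somata\n")
print("  cell        ratio    OxD      truth    error")
errors = []
for m in measurements:
    c = min(truth, key=lambda c: (c.x - m.x) ** 2 + (c.y - m.y) ** 2)
    oxd = oxd_from_ratio(m.ratio, DEFAULT_CALIBRATION)
    errors.append(oxd - c.oxd_true)
    print(f"  {m.cell_id}  {m.ratio:.4f}   {oxd:.4f}   {c.oxd_true:.4f}   {oxd - c.oxd_true:+.4f}")
print(f"\nmean absolute OxD error: {np.mean(np.abs(errors)):.4f}")
# Per-cell errors of a few hundredths reflect photon noise on ~2000
# detected photons per pixel; they average out across a population.
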