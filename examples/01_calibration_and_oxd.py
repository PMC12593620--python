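"""Converting roGFP fluorescence ratios to degrees of oxidation.

Builds the reference calibration (endpoint ratios measured under full
oxidation and full reduction plus the instrument factor), converts a few
ratios to OxD, and propagates the calibration uncertainty at one ratio.
"""

from redoxmap import (
    DEFAULT_CALIBRATION,
    oxd_from_ratio,
    propagate_calibration_uncertainty,
    ratio_from_oxd,
)

calib = DEFAULT_CALIBRATION
print(
    f"calibration: R_ox={calib.r_ox} +/- {calib.sd_r_ox} (n={calib.n_ox}), "
    f"R_red={calib.r_red} +/- {calib.sd_r_red} (n={calib.n_red}), "
    f"IF={calib.instrument_factor} +/- {calib.sd_if}"
)

# the endpoints map to OxD 0 and 1 exactly; the midpoint ratio 0.662
# collapses to 1/(1+IF) ~ 0.668
for r in (0.408, 0.577, 0.662, 0.916):
    print(f"  R = {r:.3f}  ->  OxD = {oxd_from_ratio(r, calib):.4f}")

# the exact inverse: which ratio corresponds to a half-oxidized sensor?
print(f"ratio at OxD 0.5: {ratio_from_oxd(0.5, calib):.4f}")

# Monte-Carlo propagation of the calibration SDs at the midpoint ratio
interval = propagate_calibration_uncertainty(0.662, calib, n_draws=5000, rng=0)
print(
    f"OxD at R=0.662: {interval.point:.3f} "
    f"(95 % calibration interval {interval.lo:.3f}-{interval.hi:.3f})"
)
# The interval reflects only calibration uncertainty, not photon noise:
# even a perfectly measured ratio maps to a range of plausible OxD.
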