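"""Ratio-to-OxD conversion for excitation-ratiometric roGFP imaging.

The redox-sensitive GFP (roGFP) has two excitation bands that shift
reciprocally with the oxidation state of its engineered disulfide.  The
fluorescence ratio R = F740/F910 is converted into the relative degree of
oxidation

    OxD = (R - R_red) / [ IF * (R_ox - R) + (R - R_red) ]

where R_ox and R_red are the ratios at full oxidation (strong oxidant,
H2O2) and full reduction (strong reductant, DTT), and IF is the
instrument factor F910_ox / F910_red — the change of the single-channel
910 nm intensity between the two endpoint states, a property of the
optics and wavelength settings.

Endpoint ratios and the instrument factor are estimated from endpoint
recordings of the same tissue driven to full oxidation and full
reduction (``estimate_calibration``).  The conversion and its exact
analytic inverse are ``oxd_from_ratio`` / ``ratio_from_oxd``; Monte-Carlo
propagation of the calibration uncertainties is provided by
``propagate_calibration_uncertainty``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CalibrationParams",
    "DEFAULT_CALIBRATION",
    "OxdInterval",
    "estimate_calibration",
    "oxd_from_ratio",
    "propagate_calibration_uncertainty",
    "ratio_from_oxd",
]


class CalibrationError(ValueError):
    """Raised for invalid or inconsistent calibration parameters."""


@dataclass(frozen=True)
class CalibrationParams:
    """Calibration triple of an excitation-ratiometric redox sensor.

    Parameters
    ----------
    r_ox, r_red
        Fluorescence ratio F740/F910 at full oxidation / full reduction.
    instrument_factor
        F910 intensity at full oxidation divided by F910 at full
        reduction (dimensionless; depends on excitation wavelengths,
        laser intensity settings and detection path).
    sd_r_ox, sd_r_red, sd_if
        Across-cell standard deviations of the three constants.
    n_ox, n_red
        Number of cells entering each endpoint estimate.
    """

    r_ox: float
    r_red: float
    instrument_factor: float
    sd_r_ox: float = 0.0
    sd_r_red: float = 0.0
    sd_if: float = 0.0
    n_ox: int = 1
    n_red: int = 1

    def __post_init__(self) -> None:
        if not (self.r_ox > self.r_red > 0):
            raise CalibrationError(
                f"require r_ox > r_red > 0, got r_ox={self.r_ox}, r_red={self.r_red}"
            )
        if not self.instrument_factor > 0:
            raise CalibrationError(
                f"instrument factor must be > 0, got {self.instrument_factor}"
            )
        for name in ("sd_r_ox", "sd_r_red", "sd_if"):
            if getattr(self, name) < 0:
                raise CalibrationError(f"{name} must be >= 0")
        if self.n_ox < 1 or self.n_red < 1:
            raise CalibrationError("cell counts must be >= 1")


#: Reference calibration of cytosolic roGFPc measured in the pyramidal cell
#: layer of hippocampal CA1 (H2O2 / DTT endpoint protocol): R_ox = 0.916
#: +/- 0.106 (76 cells), R_red = 0.408 +/- 0.063 (78 cells), instrument
#: factor 0.497 +/- 0.126.
DEFAULT_CALIBRATION = CalibrationParams(
    r_ox=0.916,
    r_red=0.408,
    instrument_factor=0.497,
    sd_r_ox=0.106,
    sd_r_red=0.063,
    sd_if=0.126,
    n_ox=76,
    n_red=78,
)


def oxd_from_ratio(r, calib: CalibrationParams):
    """Convert fluorescence ratios to relative degrees of oxidation.

    Evaluates OxD = (R - R_red) / [IF (R_ox - R) + (R - R_red)].

    The formula is evaluated for any ratio, including ratios outside
    [r_red, r_ox]; out-of-range inputs yield OxD outside [0, 1] and are
    left for the downstream intactness filter, never clamped here.
    Ratios for which the denominator is non-positive (possible only well
    above r_ox) return NaN as an undefined-value marker.

    Accepts scalars or arrays; returns the matching type.
    """
    r_arr = np.asarray(r, dtype=float)
    num = r_arr - calib.r_red
    den = calib.instrument_factor * (calib.r_ox - r_arr) + num
    with np.errstate(divide="ignore", invalid="ignore"):
        oxd = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(oxd)
    return oxd


def ratio_from_oxd(oxd, calib: CalibrationParams):
    """Exact analytic inverse of :func:`oxd_from_ratio` on OxD in [0, 1].

    R = [OxD * IF * R_ox + (1 - OxD) * R_red] / [OxD * IF + 1 - OxD]
    """
    x = np.asarray(oxd, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("oxd must lie in [0, 1]")
    k = calib.instrument_factor
    r = (x * k * calib.r_ox + (1.0 - x) * calib.r_red) / (x * k + 1.0 - x)
    if np.isscalar(oxd) or np.ndim(oxd) == 0:
        return float(r)
    return r


def estimate_calibration(
    ox_measurements: Sequence,
    red_measurements: Sequence,
    pairing: Literal["matched", "unmatched"] = "matched",
) -> CalibrationParams:
    """Estimate the calibration triple from endpoint ROI measurements.

    Parameters
    ----------
    ox_measurements, red_measurements
        ROI measurements (``RoiMeasurement``-like objects exposing
        ``cell_id``, ``ratio`` and ``f910_mean``) recorded at full
        oxidation and full reduction of the same tissue.
    pairing
        ``"matched"`` computes the instrument factor as the mean of the
        per-cell quotients F910_ox / F910_red over cells present in both
        endpoint recordings (per-cell pairing cancels the cell-to-cell
        expression heterogeneity); ``"unmatched"`` uses the quotient of
        the endpoint F910 means.

    Returns
    -------
    CalibrationParams with across-cell SDs and the endpoint cell counts.
    """
    ox = [m for m in ox_measurements if np.isfinite(m.ratio)]
    red = [m for m in red_measurements if np.isfinite(m.ratio)]
    if not ox or not red:
        raise CalibrationError("need at least one finite measurement per endpoint")

    r_ox_vals = np.array([m.ratio for m in ox])
    r_red_vals = np.array([m.ratio for m in red])
    r_ox = float(np.mean(r_ox_vals))
    r_red = float(np.mean(r_red_vals))
    if r_ox <= 0 or r_red <= 0:
        raise CalibrationError("endpoint mean ratios must be positive")

    if pairing == "matched":
        ox_by_id = {m.cell_id: m for m in ox}
        red_by_id = {m.cell_id: m for m in red}
        shared = sorted(set(ox_by_id) & set(red_by_id))
        if not shared:
            raise CalibrationError("matched pairing requires shared cell_ids")
        quotients = np.array(
            [ox_by_id[c].f910_mean / red_by_id[c].f910_mean for c in shared]
        )
        inst = float(np.mean(quotients))
        sd_if = float(np.std(quotients, ddof=1)) if len(quotients) > 1 else 0.0
    elif pairing == "unmatched":
        f_ox = np.array([m.f910_mean for m in ox])
        f_red = np.array([m.f910_mean for m in red])
        inst = float(np.mean(f_ox) / np.mean(f_red))
        # delta-method SD of a ratio of independent means
        cv2 = 0.0
        if len(f_ox) > 1:
            cv2 += np.var(f_ox, ddof=1) / len(f_ox) / np.mean(f_ox) ** 2
        if len(f_red) > 1:
            cv2 += np.var(f_red, ddof=1) / len(f_red) / np.mean(f_red) ** 2
        sd_if = float(inst * np.sqrt(cv2))
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown pairing {pairing!r}")

    return CalibrationParams(
        r_ox=r_ox,
        r_red=r_red,
        instrument_factor=inst,
        sd_r_ox=float(np.std(r_ox_vals, ddof=1)) if len(r_ox_vals) > 1 else 0.0,
        sd_r_red=float(np.std(r_red_vals, ddof=1)) if len(r_red_vals) > 1 else 0.0,
        sd_if=sd_if,
        n_ox=len(ox),
        n_red=len(red),
    )


@dataclass(frozen=True)
class OxdInterval:
    """OxD point estimate with a Monte-Carlo 95 % interval."""

    point: float
    lo: float
    hi: float
    n_valid_draws: int


def propagate_calibration_uncertainty(
    r: float,
    calib: CalibrationParams,
    n_draws: int = 2000,
    rng=None,
) -> OxdInterval:
    """Propagate calibration SDs into an OxD interval at ratio ``r``.

    Draws calibration triples from independent normals centred on the
    calibration means, discards physically invalid draws (r_ox <= r_red,
    non-positive values), evaluates the conversion for each valid draw
    and reports the median and central 95 % interval.

    Raises
    ------
    CalibrationError
        If more than half of the draws are invalid — the calibration is
        then too uncertain for meaningful propagation.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    rng = np.random.default_rng(rng)
    r_ox = rng.normal(calib.r_ox, calib.sd_r_ox, n_draws)
    r_red = rng.normal(calib.r_red, calib.sd_r_red, n_draws)
    inst = rng.normal(calib.instrument_factor, calib.sd_if, n_draws)
    valid = (r_ox > r_red) & (r_red > 0) & (inst > 0)
    if valid.sum() < n_draws / 2:
        raise CalibrationError(
            f"calibration too uncertain: {n_draws - int(valid.sum())}/{n_draws} "
            "invalid draws"
        )
    num = r - r_red[valid]
    den = inst[valid] * (r_ox[valid] - r) + num
    oxd = num / den
    oxd = oxd[np.isfinite(oxd) & (den > 0)]
    point = float(np.median(oxd))
    lo, hi = np.percentile(oxd, [2.5, 97.5])
    return OxdInterval(point=point, lo=float(lo), hi=float(hi), n_valid_draws=int(len(oxd)))
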