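"""Ratio-image computation and somatic ROI quantification.

A field is a registered pair of two-photon excitation channels, F740 and
F910, of the same tissue.  Quantification follows the conventions of
excitation-ratiometric imaging: a pixelwise ratio image F740/F910 is
computed first, guarded against division by dim F910 pixels, and the
per-neuron readout is the mean of the pixelwise ratios within a circular
somatic ROI.  A 12-bit pseudocolor display rendering (ratio x 1000) is
provided for visualisation only and never feeds back into quantification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "CircularRoi",
    "FieldImage",
    "RatioImage",
    "RoiMeasurement",
    "compute_ratio_image",
    "detect_somata",
    "estimate_f910_floor",
    "measure_rois",
    "render_ratio_display",
]

#: Reserved display index marking invalid (division-guarded) pixels.
RESERVED_DISPLAY_INDEX = 0
#: Highest index of the 12-bit pseudocolor palette.
DISPLAY_MAX = 4095


class MissingChannelError(KeyError):
    """A required image channel is absent from the field."""


@dataclass
class FieldImage:
    """Registered multi-channel image of one field of view.

    channels maps channel name (e.g. ``"F740"``, ``"F910"``, ``"nuclear"``,
    ``"immunolabel"``, ``"structural"``) to a 2-D intensity array in
    detector counts.  All channels share one pixel grid (0-based,
    row-major, origin top-left); ``pixel_size`` is in micrometres per
    pixel.  ``fiducials`` lists bleach-mark rectangles as
    ``(x, y, size)`` with (x, y) the top-left corner in pixels.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    metadata: dict = dc_field(default_factory=dict)
    fiducials: list[tuple[int, int, int]] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {ch!r} is not 2-D")
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"channel {ch!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(
                f"channel {name!r} missing; present: {sorted(self.channels)}"
            ) from None


@dataclass(frozen=True)
class CircularRoi:
    """Circular somatic region of interest, (x, y) = (column, row)."""

    cell_id: str
    x: float
    y: float
    radius: float


@dataclass(frozen=True)
class RatioImage:
    """Pixelwise F740/F910 ratio with a validity mask."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("ratio and mask shapes differ")


@dataclass(frozen=True)
class RoiMeasurement:
    """Quantified soma: channel means, ratio and QC information.

    ``ratio`` is the primary statistic: the mean of pixelwise ratios over
    valid pixels.  ``ratio_of_means`` (F740 mean / F910 mean over the
    whole ROI) is carried as a cross-check; a >5 % disagreement between
    the two raises the ``"ratio_mismatch"`` QC flag.  A ROI without any
    valid pixel reports ``ratio`` = NaN with the ``"no_valid_pixels"``
    flag rather than raising.
    """

    cell_id: str
    x: float
    y: float
    radius: float
    f740_mean: float
    f910_mean: float
    ratio: float
    ratio_of_means: float
    n_valid_pixels: int
    qc_flags: frozenset[str]


def subtract_background(field: FieldImage) -> FieldImage:
    """Subtract the diffuse background level from every channel.

    The level per channel is the median of the below-Otsu (non-soma)
    pixels — detector offset plus diffuse tissue fluorescence.  Removing
    it before ratio computation keeps soma ratios and single-channel
    means free of the additive offset that would otherwise pull ratios
    toward the background ratio.  Results are clipped at zero and
    returned as float channels; a channel without contrast is returned
    unchanged.
    """
    channels = {}
    for name, arr in field.channels.items():
        img = np.asarray(arr, dtype=float)
        smoothed = ndimage.gaussian_filter(img, 1.0)
        if smoothed.max() > smoothed.min():
            thr = filters.threshold_otsu(smoothed)
            bg = img[smoothed <= thr]
            level = float(np.median(bg)) if bg.size else 0.0
        else:
            level = 0.0
        channels[name] = np.clip(img - level, 0.0, None)
    return FieldImage(
        channels=channels,
        pixel_size=field.pixel_size,
        metadata=dict(field.metadata),
        fiducials=list(field.fiducials),
    )


def estimate_f910_floor(field: FieldImage, k: float = 3.0) -> float:
    """Estimate the F910 division floor as background mean + k * SD.

    Background pixels are taken as those below the Otsu threshold of the
    (lightly smoothed) F910 channel; on fields without foreground
    structure the whole image is treated as background.
    """
    f910 = np.asarray(field.channel("F910"), dtype=float)
    smoothed = ndimage.gaussian_filter(f910, 1.0)
    if smoothed.max() > smoothed.min():
        thr = filters.threshold_otsu(smoothed)
        bg = f910[smoothed <= thr]
        if bg.size < 16:
            bg = f910.ravel()
    else:
        bg = f910.ravel()
    return float(bg.mean() + k * bg.std())


def compute_ratio_image(field: FieldImage, f910_floor: float | None = None) -> RatioImage:
    """Compute the pixelwise F740/F910 ratio image with validity mask.

    Pixels whose F910 intensity falls below ``f910_floor`` are marked
    invalid and excluded from every downstream ROI average; valid pixels
    are guaranteed free of infinities and NaNs.  With ``f910_floor=None``
    the floor is estimated from the image background
    (:func:`estimate_f910_floor`).
    """
    f740 = np.asarray(field.channel("F740"), dtype=float)
    f910 = np.asarray(field.channel("F910"), dtype=float)
    if f910_floor is None:
        f910_floor = estimate_f910_floor(field)
    if not f910_floor > 0:
        raise ValueError("f910_floor must be > 0")
    valid = f910 >= f910_floor
    values = np.zeros_like(f740)
    np.divide(f740, f910, out=values, where=valid)
    values[~valid] = np.nan
    return RatioImage(values=values, valid=valid)


def render_ratio_display(
    ratio_image: RatioImage,
    scale: float = 1000.0,
    reserved_index: int = RESERVED_DISPLAY_INDEX,
) -> np.ndarray:
    """Map a ratio image onto the 12-bit pseudocolor index scale.

    Valid pixels map to ``round(ratio * scale)`` clipped to
    ``[1, 4095]``; index ``reserved_index`` (default 0) is reserved for
    invalid pixels.  The rendering is display-only: quantification always
    uses the unscaled ratios.
    """
    if not scale > 0:
        raise ValueError("scale must be > 0")
    idx = np.rint(np.nan_to_num(ratio_image.values, nan=0.0) * scale)
    idx = np.clip(idx, 1, DISPLAY_MAX).astype(np.uint16)
    idx[~ratio_image.valid] = reserved_index
    return idx


def detect_somata(
    field: FieldImage,
    min_radius: float = 3.0,
    max_radius: float = 15.0,
    channel: str = "F910",
    smoothing_sigma: float = 1.0,
    threshold: float | None = None,
) -> list[CircularRoi]:
    """Detect bright, roughly circular somata on a structural channel.

    The channel is smoothed, thresholded (Otsu, but never below
    background mean + 3 SD) and labelled; connected components whose
    equivalent radius lies within ``[min_radius, max_radius]`` become
    circular ROIs at their centroid.  Overlapping detections are resolved
    deterministically in favour of the larger blob, and ROIs are kept
    fully inside the image.  Deterministic for fixed input; an empty list
    is a valid result.
    """
    img = np.asarray(field.channel(channel), dtype=float)
    smoothed = ndimage.gaussian_filter(img, smoothing_sigma)
    if smoothed.max() <= smoothed.min():
        return []
    if threshold is None:
        thr = float(filters.threshold_otsu(smoothed))
        bg = smoothed[smoothed <= thr]
        if bg.size:
            thr = max(thr, float(bg.mean() + 3.0 * bg.std()))
        threshold = thr
    mask = smoothed > threshold
    labels, _ = ndimage.label(mask)
    rois: list[CircularRoi] = []
    h, w = img.shape
    props = measure.regionprops(labels, intensity_image=img)
    # larger blobs first; ties broken by position for determinism
    props.sort(key=lambda p: (-p.area, p.centroid))
    for prop in props:
        radius = float(np.sqrt(prop.area / np.pi))
        if not (min_radius <= radius <= max_radius):
            continue
        cy, cx = prop.centroid
        if cx - radius < 0 or cy - radius < 0 or cx + radius > w - 1 or cy + radius > h - 1:
            continue
        if any(
            np.hypot(cx - r.x, cy - r.y) < radius + r.radius for r in rois
        ):
            continue
        rois.append(CircularRoi(cell_id=f"roi{len(rois):04d}", x=cx, y=cy, radius=radius))
    return rois


def _disk_mask(shape: tuple[int, int], x: float, y: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - x) ** 2 + (yy - y) ** 2 <= radius**2


def measure_rois(
    field: FieldImage,
    ratio_image: RatioImage,
    rois: Sequence[CircularRoi],
    saturation_fraction: float = 0.98,
    min_valid_fraction: float = 0.5,
) -> list[RoiMeasurement]:
    """Average the ratio image and channel intensities within each ROI.

    QC flags: ``"low_validity"`` when fewer than ``min_valid_fraction``
    of the ROI pixels are valid, ``"saturation"`` when either channel
    mean lies within 2 % of the detector maximum, ``"ratio_mismatch"``
    when mean-of-ratios and ratio-of-means disagree by more than 5 %,
    ``"no_valid_pixels"`` when the ROI contains no valid ratio pixel.
    """
    f740 = np.asarray(field.channel("F740"), dtype=float)
    f910 = np.asarray(field.channel("F910"), dtype=float)
    if np.issubdtype(field.channel("F910").dtype, np.integer):
        dtype_max = float(np.iinfo(field.channel("F910").dtype).max)
    else:
        dtype_max = float(field.metadata.get("dtype_max", np.inf))
    out: list[RoiMeasurement] = []
    for roi in rois:
        mask = _disk_mask(field.shape, roi.x, roi.y, roi.radius)
        n_pix = int(mask.sum())
        if n_pix == 0:
            raise ValueError(f"ROI {roi.cell_id} lies outside the image")
        valid = mask & ratio_image.valid
        n_valid = int(valid.sum())
        f740_mean = float(f740[mask].mean())
        f910_mean = float(f910[mask].mean())
        ratio_of_means = f740_mean / f910_mean if f910_mean > 0 else np.nan
        flags: set[str] = set()
        if n_valid == 0:
            ratio = float("nan")
            flags.add("no_valid_pixels")
        else:
            ratio = float(ratio_image.values[valid].mean())
            if np.isfinite(ratio_of_means) and ratio > 0:
                if abs(ratio - ratio_of_means) / ratio > 0.05:
                    flags.add("ratio_mismatch")
        if n_valid < min_valid_fraction * n_pix:
            flags.add("low_validity")
        if np.isfinite(dtype_max) and (
            f740_mean >= saturation_fraction * dtype_max
            or f910_mean >= saturation_fraction * dtype_max
        ):
            flags.add("saturation")
        out.append(
            RoiMeasurement(
                cell_id=roi.cell_id,
                x=roi.x,
                y=roi.y,
                radius=roi.radius,
                f740_mean=f740_mean,
                f910_mean=f910_mean,
                ratio=ratio,
                ratio_of_means=float(ratio_of_means),
                n_valid_pixels=n_valid,
                qc_flags=frozenset(flags),
            )
        )
    return out


def shrink_rois(rois: Iterable[CircularRoi], factor: float = 0.8, min_radius: float = 2.0) -> list[CircularRoi]:
    """Shrink ROI radii toward the soma centre.

    Restricting the average to the ROI core avoids edge pixels whose
    signal mixes with background through the optical blur.
    """
    return [
        dataclasses.replace(r, radius=max(min_radius, r.radius * factor)) for r in rois
    ]
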