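"""Seeded synthetic two-photon redox-imaging data.

Generates multi-channel fields of roGFP-expressing neuron somata with
known ground truth, so that every stage of the analysis pipeline —
ratio computation, OxD calibration, filtering, statistics and the
correlative MeCP2 stage — can be exercised and validated without any
acquisition hardware.

The forward model is a linear two-state fluorophore: the oxidized and
reduced sensor species emit with fixed coefficients in each excitation
channel, so a soma at degree of oxidation ``x`` has channel intensities

    F740  ∝  a_ox * x + a_red * (1 - x)
    F910  ∝  b_ox * x + b_red * (1 - x)

whose ratio interpolates between R_red = a_red/b_red and
R_ox = a_ox/b_ox.  The analytic inverse of this forward model is exactly
the OxD conversion formula used by the calibration module, which makes
the generator a closed-loop oracle for the whole pipeline.

Detection noise follows the standard photon-limited model: Poisson shot
noise on the expected counts, additive Gaussian read noise, and a
constant background offset.  Somata are uniform disks with a Gaussian
blur standing in for the point-spread function; a diffuse "neuropil"
baseline provides the tissue signal against which bleach-mark fiducials
are visible as dark squares.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .calibration import CalibrationParams, DEFAULT_CALIBRATION
from .ratiometric import FieldImage

__all__ = [
    "DEFAULT_GROUP_OXD",
    "FluorophoreModel",
    "GroundTruthCell",
    "PackingError",
    "SimScenario",
    "cells_to_frame",
    "expected_ratio",
    "make_fluorophore_model",
    "simulate_calibration_endpoints",
    "simulate_correlative_slice",
    "simulate_field",
    "simulate_mosaic_labels",
    "stamp_bleach_mark",
]

REGIONS = (
    "CA1",
    "CA3",
    "DG",
    "S",
    "visual",
    "auditory",
    "somatosensory",
    "RSA",
    "Ect",
    "motor",
)
GENOTYPES = ("WT", "Mecp2+/-")
AGE_GROUPS = ("p50", "gt_p100")

# Ground-truth OxD (mean, SD) per (region, genotype, age group).  Means
# follow the measured slice-level redox baselines of the study system;
# for CA1 and DG WT p50 the cell-level values (0.466 +/- 0.172 and
# 0.719 +/- 0.132) are used since those groups were also reported per
# neuron.  Cell-level SD defaults to 0.15 where only slice-level spread
# was reported.
_CELL_SD = 0.15
_TABLE_MEANS = {
    # region: (WT p50, Mecp2 p50, WT >p100, Mecp2 >p100)
    "CA1": (0.466, 0.428, 0.337, 0.409),
    "CA3": (0.719, 0.664, 0.689, 0.770),
    "DG": (0.719, 0.721, 0.660, 0.743),
    "S": (0.699, 0.551, 0.540, 0.557),
    "visual": (0.568, 0.557, 0.446, 0.549),
    "auditory": (0.632, 0.535, 0.411, 0.537),
    "somatosensory": (0.593, 0.525, 0.465, 0.518),
    "RSA": (0.571, 0.573, 0.493, 0.621),
    "Ect": (0.702, 0.621, 0.495, 0.610),
    "motor": (0.628, 0.553, 0.450, 0.575),
}
DEFAULT_GROUP_OXD: dict[tuple[str, str, str], tuple[float, float]] = {}
for _region, _means in _TABLE_MEANS.items():
    for _i, (_gt, _age) in enumerate(
        [("WT", "p50"), ("Mecp2+/-", "p50"), ("WT", "gt_p100"), ("Mecp2+/-", "gt_p100")]
    ):
        _sd = _CELL_SD
        if (_region, _gt, _age) == ("CA1", "WT", "p50"):
            _sd = 0.172
        elif (_region, _gt, _age) == ("DG", "WT", "p50"):
            _sd = 0.132
        DEFAULT_GROUP_OXD[(_region, _gt, _age)] = (_means[_i], _sd)


class PackingError(RuntimeError):
    """Requested number of somata cannot be placed without overlap."""


@dataclass(frozen=True)
class FluorophoreModel:
    """Linear two-state emission model of the ratiometric sensor.

    ``a_ox``/``a_red`` are the emission coefficients of the oxidized and
    reduced species under 740 nm excitation, ``b_ox``/``b_red`` under
    910 nm excitation (arbitrary fluorescence units per unit sensor).
    """

    a_ox: float
    a_red: float
    b_ox: float
    b_red: float

    def __post_init__(self) -> None:
        for name in ("a_ox", "a_red", "b_ox", "b_red"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.a_ox / self.b_ox > self.a_red / self.b_red:
            raise ValueError(
                "oxidation must raise the F740/F910 ratio (a_ox/b_ox > a_red/b_red)"
            )

    @property
    def r_ox(self) -> float:
        return self.a_ox / self.b_ox

    @property
    def r_red(self) -> float:
        return self.a_red / self.b_red

    @property
    def instrument_factor(self) -> float:
        return self.b_ox / self.b_red

    def calibration(self) -> CalibrationParams:
        """The calibration triple implied by the emission coefficients."""
        return CalibrationParams(
            r_ox=self.r_ox, r_red=self.r_red, instrument_factor=self.instrument_factor
        )

    def channel_intensities(self, oxd) -> tuple[np.ndarray, np.ndarray]:
        """Relative (F740, F910) intensities, normalised so F910 = 1 at OxD 0."""
        x = np.asarray(oxd, dtype=float)
        i740 = (self.a_ox * x + self.a_red * (1.0 - x)) / self.b_red
        i910 = (self.b_ox * x + self.b_red * (1.0 - x)) / self.b_red
        return i740, i910


def make_fluorophore_model(
    calib: CalibrationParams, b_red_scale: float = 1.0
) -> FluorophoreModel:
    """Invert a calibration triple into forward emission coefficients.

    The returned model reproduces the calibration exactly:
    a_ox = R_ox * IF * s, a_red = R_red * s, b_ox = IF * s, b_red = s
    with s = ``b_red_scale``.
    """
    if not b_red_scale > 0:
        raise ValueError("b_red_scale must be positive")
    return FluorophoreModel(
        a_ox=calib.r_ox * calib.instrument_factor * b_red_scale,
        a_red=calib.r_red * b_red_scale,
        b_ox=calib.instrument_factor * b_red_scale,
        b_red=b_red_scale,
    )


def expected_ratio(model: FluorophoreModel, oxd):
    """Noise-free F740/F910 ratio at a given degree of oxidation.

    Strictly increasing in OxD, from R_red at 0 to R_ox at 1.
    """
    x = np.asarray(oxd, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("oxd must lie in [0, 1]")
    i740, i910 = model.channel_intensities(x)
    r = i740 / i910
    if np.isscalar(oxd) or np.ndim(oxd) == 0:
        return float(r)
    return r


@dataclass(frozen=True)
class GroundTruthCell:
    """One simulated soma with its ground truth."""

    cell_id: str
    x: float
    y: float
    radius: float
    oxd_true: float
    expression: float
    slice_id: str
    region: str
    genotype: str
    age_group: str
    mecp2_positive: bool | None = None
    ratio_true: float | None = None


def cells_to_frame(cells: Sequence[GroundTruthCell]):
    """Ground-truth cells as a pandas DataFrame (one row per soma)."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(c) for c in cells])


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for the synthetic generator.

    ``group_oxd`` maps (region, genotype, age_group) to the ground-truth
    OxD (mean, SD) of that population; draws are truncated to
    [0.02, 0.98] to keep the ratio conversion well conditioned (inside
    the downstream 5–95 % intactness screen).  ``photon_scale`` is the
    expected F910 photon count of a unit-expression soma at OxD = 0;
    ``numpy.inf`` disables all noise sources and yields float images.
    ``mcat_effect`` multiplicatively suppresses the genotype OxD shift
    relative to wild type (1.0 = no transgene, 0.0 = shift abolished).
    """

    group_oxd: Mapping[tuple[str, str, str], tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_GROUP_OXD)
    )
    cells_per_field: int = 14
    fields_per_slice: int = 4
    slices_per_group: int = 3
    mosaic_fraction: float = 0.45
    clone_count: int = 150
    photon_scale: float = 2000.0
    read_noise_sd: float = 3.0
    background: float = 10.0
    neuropil_level: float = 0.1
    expression_sigma: float = 0.3
    image_shape: tuple[int, int] = (256, 256)
    soma_radius: float = 6.0
    psf_sigma: float = 1.0
    mcat_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mosaic_fraction < 1):
            raise ValueError("mosaic_fraction must lie in (0, 1)")
        if self.clone_count < 1:
            raise ValueError("clone_count must be >= 1")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be > 0")
        if self.cells_per_field < 0:
            raise ValueError("cells_per_field must be >= 0")
        for key, (mean, sd) in self.group_oxd.items():
            if not (0 < mean < 1):
                raise ValueError(f"group {key}: OxD mean {mean} outside (0, 1)")
            if sd < 0:
                raise ValueError(f"group {key}: negative SD")
        if min(self.image_shape) < 8 * self.soma_radius:
            raise ValueError("image dimensions must be >= 4x the soma diameter")

    def group_mean_sd(self, region: str, genotype: str, age_group: str) -> tuple[float, float]:
        """Effective (mean, SD) for a group, with the mCAT suppression applied."""
        mean, sd = self.group_oxd[(region, genotype, age_group)]
        if genotype != "WT" and self.mcat_effect != 1.0:
            wt_mean, _ = self.group_oxd[(region, "WT", age_group)]
            mean = wt_mean + self.mcat_effect * (mean - wt_mean)
        return mean, sd


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators so toggling one noise source leaves
    the draws of the others unchanged."""
    children = np.random.SeedSequence([int(seed)]).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _place_somata(
    n: int,
    shape: tuple[int, int],
    radius: float,
    rng: np.random.Generator,
    min_separation: float = 2.0,
    max_tries_per_cell: int = 400,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping disk positions (never silently fewer)."""
    h, w = shape
    margin = radius * 1.1 + 4.0
    placed: list[tuple[float, float, float]] = []
    tries = 0
    while len(placed) < n:
        if tries > max_tries_per_cell * max(n, 1):
            raise PackingError(
                f"could not place {n} somata of radius {radius} in a {shape} image"
            )
        tries += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        r = radius * rng.uniform(0.9, 1.1)
        if all(
            np.hypot(x - px, y - py) >= r + pr + min_separation
            for px, py, pr in placed
        ):
            placed.append((x, y, r))
    return placed


def _truncnorm_oxd(
    mean: float, sd: float, n: int, rng: np.random.Generator, lo: float = 0.02, hi: float = 0.98
) -> np.ndarray:
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _lognormal_unit_mean(sigma: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative heterogeneity factor with mean exactly one."""
    if sigma == 0:
        return np.ones(n)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _paint_disks(
    shape: tuple[int, int],
    cells: Sequence[tuple[float, float, float]],
    amplitudes: np.ndarray,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    h, w = shape
    for (x, y, r), amp in zip(cells, amplitudes):
        x0, x1 = max(0, int(x - r - 2)), min(w, int(x + r + 3))
        y0, y1 = max(0, int(y - r - 2)), min(h, int(y + r + 3))
        yy, xx = np.ogrid[y0:y1, x0:x1]
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
        img[y0:y1, x0:x1][mask] += amp
    return img


def _render_channels(
    i740: np.ndarray,
    i910: np.ndarray,
    geometry: Sequence[tuple[float, float, float]],
    expression: np.ndarray,
    scenario: SimScenario,
    noise_rng: np.random.Generator,
    neuropil_ratio: float,
) -> dict[str, np.ndarray]:
    """Render an F740/F910 pair from per-cell relative intensities."""
    shape = scenario.image_shape
    noise_free = not np.isfinite(scenario.photon_scale)
    scale = 1.0 if noise_free else scenario.photon_scale
    f740 = _paint_disks(shape, geometry, expression * i740 * scale)
    f910 = _paint_disks(shape, geometry, expression * i910 * scale)
    if scenario.psf_sigma > 0:
        f740 = ndimage.gaussian_filter(f740, scenario.psf_sigma)
        f910 = ndimage.gaussian_filter(f910, scenario.psf_sigma)
    if scenario.neuropil_level > 0:
        f910 += scenario.neuropil_level * scale
        f740 += scenario.neuropil_level * scale * neuropil_ratio
    f740 += scenario.background if not noise_free else 0.0
    f910 += scenario.background if not noise_free else 0.0
    if noise_free:
        return {"F740": f740, "F910": f910}
    out = {}
    for name, expected in (("F740", f740), ("F910", f910)):
        counts = noise_rng.poisson(expected).astype(float)
        counts += noise_rng.normal(0.0, scenario.read_noise_sd, size=shape)
        out[name] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return out


def simulate_field(
    scenario: SimScenario,
    model: FluorophoreModel,
    slice_id: str = "s0",
    region: str = "CA1",
    genotype: str = "WT",
    age_group: str = "p50",
    seed: int = 0,
    field_id: str = "f0",
    n_cells: int | None = None,
) -> tuple[FieldImage, list[GroundTruthCell]]:
    """Simulate one registered F740/F910 field with ground truth.

    Somata are placed without overlap, each receives a ground-truth OxD
    drawn from the group's truncated normal and a unit-mean lognormal
    expression factor; channels are rendered as photon-count images (see
    module docstring for the noise model) and are pixel-registered by
    construction.

    Raises
    ------
    PackingError
        If the requested number of somata cannot be placed.
    """
    n = scenario.cells_per_field if n_cells is None else n_cells
    place_rng, oxd_rng, expr_rng, noise_rng = _substreams(seed, 4)
    geometry = _place_somata(n, scenario.image_shape, scenario.soma_radius, place_rng)
    mean, sd = scenario.group_mean_sd(region, genotype, age_group)
    oxd = _truncnorm_oxd(mean, sd, n, oxd_rng)
    expression = _lognormal_unit_mean(scenario.expression_sigma, n, expr_rng)
    i740, i910 = model.channel_intensities(oxd)
    channels = _render_channels(
        i740, i910, geometry, expression, scenario, noise_rng,
        neuropil_ratio=expected_ratio(model, float(np.clip(mean, 0, 1))),
    )
    field = FieldImage(
        channels=channels,
        metadata={
            "slice_id": slice_id,
            "field_id": field_id,
            "region": region,
            "genotype": genotype,
            "age_group": age_group,
            "state": "baseline",
            "seed": int(seed),
        },
    )
    cells = [
        GroundTruthCell(
            cell_id=f"{slice_id}_{field_id}_c{i:03d}",
            x=gx,
            y=gy,
            radius=gr,
            oxd_true=float(ox),
            expression=float(ex),
            slice_id=slice_id,
            region=region,
            genotype=genotype,
            age_group=age_group,
            ratio_true=float(expected_ratio(model, float(ox))),
        )
        for i, ((gx, gy, gr), ox, ex) in enumerate(zip(geometry, oxd, expression))
    ]
    return field, cells


def simulate_mosaic_labels(
    cells: Sequence[GroundTruthCell],
    mosaic_fraction: float,
    clone_count: int,
    seed: int = 0,
    bounds: tuple[float, float, float, float] | None = None,
) -> list[GroundTruthCell]:
    """Assign MeCP2 status by a spatial X-inactivation clone model.

    Each of ``clone_count`` progenitor clones gets a random seed point
    and is MeCP2-positive with probability ``mosaic_fraction``; every
    cell inherits the status of its nearest clone seed.  With many more
    clones than cells this degenerates to independent Bernoulli draws
    per cell; with one clone all cells share a single status.  The
    expected positive fraction is ``mosaic_fraction`` either way.
    """
    if not (0 < mosaic_fraction < 1):
        raise ValueError("mosaic_fraction must lie in (0, 1)")
    if clone_count < 1:
        raise ValueError("clone_count must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    if not cells:
        return []
    xs = np.array([c.x for c in cells])
    ys = np.array([c.y for c in cells])
    if bounds is None:
        bounds = (xs.min(), ys.min(), xs.max(), ys.max())
    x0, y0, x1, y1 = bounds
    seeds_x = rng.uniform(x0, x1 if x1 > x0 else x0 + 1, clone_count)
    seeds_y = rng.uniform(y0, y1 if y1 > y0 else y0 + 1, clone_count)
    clone_status = rng.random(clone_count) < mosaic_fraction
    from scipy.spatial import cKDTree

    _, nearest = cKDTree(np.column_stack([seeds_x, seeds_y])).query(
        np.column_stack([xs, ys]), k=1
    )
    return [
        dataclasses.replace(c, mecp2_positive=bool(clone_status[k]))
        for c, k in zip(cells, nearest)
    ]


def simulate_calibration_endpoints(
    scenario: SimScenario,
    model: FluorophoreModel,
    n_ox_cells: int,
    n_red_cells: int,
    seed: int = 0,
    slice_id: str = "calib",
) -> tuple[FieldImage, FieldImage, list[GroundTruthCell], list[GroundTruthCell]]:
    """Render the same field at full oxidation and at full reduction.

    Emulates the endpoint protocol in which one slice is driven fully
    oxidized (H2O2) and, after wash-out, fully reduced (DTT).  The two
    renders share soma geometry and per-cell expression factors for the
    first ``min(n_ox_cells, n_red_cells)`` cells (same cell_ids), so the
    instrument factor is estimable from matched per-cell F910 quotients.
    """
    if n_ox_cells < 1 or n_red_cells < 1:
        raise ValueError("need at least one cell per endpoint")
    n = max(n_ox_cells, n_red_cells)
    place_rng, expr_rng, noise_ox_rng, noise_red_rng = _substreams(seed, 4)
    geometry = _place_somata(n, scenario.image_shape, scenario.soma_radius, place_rng)
    expression = _lognormal_unit_mean(scenario.expression_sigma, n, expr_rng)

    def _endpoint(n_cells: int, oxd_value: float, state: str, rng) -> tuple[FieldImage, list[GroundTruthCell]]:
        geo = geometry[:n_cells]
        expr = expression[:n_cells]
        oxd = np.full(n_cells, oxd_value)
        i740, i910 = model.channel_intensities(oxd)
        channels = _render_channels(
            i740, i910, geo, expr, scenario, rng,
            neuropil_ratio=expected_ratio(model, oxd_value),
        )
        f = FieldImage(
            channels=channels,
            metadata={"slice_id": slice_id, "state": state, "seed": int(seed)},
        )
        cells = [
            GroundTruthCell(
                cell_id=f"{slice_id}_c{i:03d}",
                x=gx,
                y=gy,
                radius=gr,
                oxd_true=oxd_value,
                expression=float(ex),
                slice_id=slice_id,
                region="CA1",
                genotype="WT",
                age_group="p50",
                ratio_true=float(expected_ratio(model, oxd_value)),
            )
            for i, ((gx, gy, gr), ex) in enumerate(zip(geo, expr))
        ]
        return f, cells

    ox_field, ox_cells = _endpoint(n_ox_cells, 1.0, "H2O2", noise_ox_rng)
    red_field, red_cells = _endpoint(n_red_cells, 0.0, "DTT", noise_red_rng)
    return ox_field, red_field, ox_cells, red_cells


def stamp_bleach_mark(
    field: FieldImage,
    corner: tuple[int, int],
    size: int,
    level: float | None = None,
) -> FieldImage:
    """Stamp a square bleach-mark fiducial into every channel.

    The mark (top-left ``corner`` = (x, y), side ``size`` pixels) is set
    to the background level — by default the 5th intensity percentile of
    each channel — and its geometry is recorded in ``field.fiducials``.
    ``size = 0`` returns the field unchanged.  A mark extending beyond
    the image raises ``ValueError``.
    """
    if size < 0:
        raise ValueError("size must be >= 0")
    if size == 0:
        return field
    x, y = corner
    h, w = field.shape
    if x < 0 or y < 0 or x + size > w or y + size > h:
        raise ValueError(f"bleach mark {corner} size {size} exceeds image {field.shape}")
    channels = {}
    for name, arr in field.channels.items():
        out = arr.copy()
        fill = np.percentile(arr, 5) if level is None else level
        out[y : y + size, x : x + size] = np.asarray(fill).astype(arr.dtype)
        channels[name] = out
    return FieldImage(
        channels=channels,
        pixel_size=field.pixel_size,
        metadata=dict(field.metadata),
        fiducials=[*field.fiducials, (int(x), int(y), int(size))],
    )


def simulate_correlative_slice(
    n_deficient: int,
    n_positive: int,
    effect: float = 1.101,
    base_ratio: float = 0.58,
    cell_sigma: float = 0.30,
    scenario: SimScenario | None = None,
    shift: tuple[int, int] | None = None,
    jitter_sd: float = 1.0,
    label_contrast: float = 10.0,
    label_sigma: float = 0.25,
    mark: tuple[int, int, int] = (10, 10, 30),
    slice_id: str = "s0",
    seed: int = 0,
) -> tuple[FieldImage, FieldImage, list[GroundTruthCell]]:
    """Simulate a live/fixed field pair for correlative redox microscopy.

    The live field carries the F740/F910 ratio channels; the fixed field
    (recorded after fixation and immunostaining) carries ``nuclear``,
    ``immunolabel`` and ``structural`` channels, globally translated by
    ``shift`` (drawn in [-8, 8] px per axis when None) with per-nucleus
    jitter.  Both carry the same bleach-mark fiducial.

    MeCP2-positive cells draw their true ratio as ``base_ratio`` times a
    unit-mean lognormal; each MeCP2-deficient cell draws
    ``effect * (slice positive mean) * lognormal``, i.e. the
    deficient-vs-positive effect is multiplicative on the slice's
    positive-cell mean, mirroring the per-slice normalisation that the
    analysis applies.
    """
    scenario = scenario or SimScenario(image_shape=(360, 360))
    n = n_deficient + n_positive
    place_rng, ratio_rng, expr_rng, noise_rng, geom_rng = _substreams(seed, 5)
    geometry = _place_somata(n, scenario.image_shape, scenario.soma_radius, place_rng)
    status = np.zeros(n, dtype=bool)
    status[ratio_rng.choice(n, size=n_positive, replace=False)] = True

    ratios = np.empty(n)
    eps = _lognormal_unit_mean(cell_sigma, n, ratio_rng)
    ratios[status] = base_ratio * eps[status]
    pos_mean = float(ratios[status].mean()) if n_positive else base_ratio
    ratios[~status] = effect * pos_mean * eps[~status]

    expression = _lognormal_unit_mean(scenario.expression_sigma, n, expr_rng)
    i910 = np.ones(n)
    i740 = ratios  # F740 = ratio * F910 by construction
    live_channels = _render_channels(
        i740, i910, geometry, expression, scenario, noise_rng,
        neuropil_ratio=base_ratio,
    )
    live = FieldImage(
        channels=live_channels,
        metadata={"slice_id": slice_id, "state": "baseline", "seed": int(seed)},
    )
    # bleaching destroys the fluorophores: only the detector offset remains
    mark_level = 0.0 if not np.isfinite(scenario.photon_scale) else scenario.background
    live = stamp_bleach_mark(live, (mark[0], mark[1]), mark[2], level=mark_level)

    if shift is None:
        shift = tuple(int(v) for v in geom_rng.integers(-8, 9, size=2))
    sx, sy = shift
    jitter = geom_rng.normal(0.0, jitter_sd, size=(n, 2))
    fixed_geom = [
        (x + sx + jx, y + sy + jy, r) for (x, y, r), (jx, jy) in zip(geometry, jitter)
    ]
    nuc_geom = [(x, y, 0.55 * r) for x, y, r in fixed_geom]
    nuc_expr = _lognormal_unit_mean(0.15, n, expr_rng)
    label_expr = _lognormal_unit_mean(label_sigma, n, expr_rng)
    label_amp = np.where(status, label_contrast, 1.0) * 0.08 * label_expr
    scale = 1.0 if not np.isfinite(scenario.photon_scale) else scenario.photon_scale
    noise_free = not np.isfinite(scenario.photon_scale)

    def _fixed_channel(geo, amps, neuropil: float) -> np.ndarray:
        img = _paint_disks(scenario.image_shape, geo, amps * scale)
        if scenario.psf_sigma > 0:
            img = ndimage.gaussian_filter(img, scenario.psf_sigma)
        img += neuropil * scale
        if noise_free:
            return img
        img += scenario.background
        counts = noise_rng.poisson(img).astype(float)
        counts += noise_rng.normal(0.0, scenario.read_noise_sd, size=img.shape)
        return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)

    fixed = FieldImage(
        channels={
            "nuclear": _fixed_channel(nuc_geom, 0.8 * nuc_expr, 0.02),
            "immunolabel": _fixed_channel(nuc_geom, label_amp, 0.01),
            "structural": _fixed_channel(fixed_geom, expression, scenario.neuropil_level),
        },
        metadata={"slice_id": slice_id, "state": "fixed", "shift": (int(sx), int(sy))},
    )
    fx, fy = mark[0] + sx, mark[1] + sy
    h, w = scenario.image_shape
    fx = int(np.clip(fx, 0, w - mark[2]))
    fy = int(np.clip(fy, 0, h - mark[2]))
    fixed = stamp_bleach_mark(fixed, (fx, fy), mark[2], level=mark_level)

    cells = [
        GroundTruthCell(
            cell_id=f"{slice_id}_c{i:03d}",
            x=gx,
            y=gy,
            radius=gr,
            oxd_true=float("nan"),
            expression=float(ex),
            slice_id=slice_id,
            region="somatosensory",
            genotype="Mecp2+/-",
            age_group="p50",
            mecp2_positive=bool(st),
            ratio_true=float(rt),
        )
        for i, ((gx, gy, gr), ex, st, rt) in enumerate(
            zip(geometry, expression, status, ratios)
        )
    ]
    return live, fixed, cells
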