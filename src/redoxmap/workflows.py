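"""End-to-end recovery experiments on synthetic data.

Each function here runs the *full* analysis path — image rendering,
soma detection, ratio quantification, calibration / OxD conversion,
screening and aggregation — against a generator whose ground truth is
set to the study conditions, and reports what the pipeline recovers.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration as cal
from . import correlative, ratiometric, stats, synthdata

__all__ = [
    "quantify_field",
    "recover_calibration",
    "recover_correlative",
    "recover_group_mean",
    "recover_slice_level",
]


def quantify_field(
    field: ratiometric.FieldImage,
    f910_floor: float | None = None,
    min_radius: float = 3.0,
    max_radius: float = 15.0,
    core_fraction: float = 0.75,
    background_subtract: bool = True,
) -> list[ratiometric.RoiMeasurement]:
    """Detect somata and measure ratio ROIs on one field.

    The diffuse background level is subtracted per channel first (so
    ratios and channel means reflect soma signal alone), and
    measurements are taken on the ROI core (``core_fraction`` of the
    detected radius) to keep blur-mixed edge pixels out of the average.
    """
    if background_subtract:
        field = ratiometric.subtract_background(field)
    ratio = ratiometric.compute_ratio_image(field, f910_floor=f910_floor)
    rois = ratiometric.detect_somata(field, min_radius=min_radius, max_radius=max_radius)
    rois = ratiometric.shrink_rois(rois, factor=core_fraction)
    return ratiometric.measure_rois(field, ratio, rois)


def _seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence([int(seed)])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def recover_calibration(
    truth: cal.CalibrationParams = cal.DEFAULT_CALIBRATION,
    n_ox: int = 76,
    n_red: int = 78,
    seed: int = 0,
    scenario: synthdata.SimScenario | None = None,
) -> cal.CalibrationParams:
    """Simulate one endpoint-calibration session and re-estimate the triple.

    Renders the oxidized (H2O2) and reduced (DTT) endpoint recordings of
    one field from the forward model implied by ``truth``, quantifies
    both with the standard detection path, pairs cells across the two
    states by position, and runs the matched calibration estimator.
    """
    scenario = scenario or synthdata.SimScenario(image_shape=(420, 420))
    model = synthdata.make_fluorophore_model(truth)
    ox_field, red_field, _, _ = synthdata.simulate_calibration_endpoints(
        scenario, model, n_ox, n_red, seed=seed
    )
    ox_meas = quantify_field(ox_field)
    red_meas = quantify_field(red_field)
    # pair detections across the two states by position (same geometry)
    red_rois = [
        ratiometric.CircularRoi(cell_id=m.cell_id, x=m.x, y=m.y, radius=m.radius)
        for m in red_meas
    ]
    matches = correlative.match_cells(
        [ratiometric.CircularRoi(m.cell_id, m.x, m.y, m.radius) for m in ox_meas],
        red_rois,
        offset=(0.0, 0.0),
        matching_radius=scenario.soma_radius,
    )
    import dataclasses

    matched_red_id = {
        row["nucleus_id"]: row["cell_id"]
        for _, row in matches[matches["matched"]].iterrows()
    }
    # matched red cells inherit the ox-state cell_id so the estimator can
    # pair them; unmatched ones keep a distinct prefix
    renamed_red = [
        dataclasses.replace(
            m, cell_id=matched_red_id.get(m.cell_id, f"red_{m.cell_id}")
        )
        for m in red_meas
    ]
    return cal.estimate_calibration(ox_meas, renamed_red, pairing="matched")


def _measurements_to_cells(
    measurements, metadata: dict, calib: cal.CalibrationParams
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "cell_id": f"{metadata.get('slice_id', 's0')}_{metadata.get('field_id', 'f0')}_{m.cell_id}",
                "slice_id": metadata.get("slice_id", "s0"),
                "region": metadata.get("region", ""),
                "genotype": metadata.get("genotype", ""),
                "age_group": metadata.get("age_group", ""),
                "ratio": m.ratio,
                "oxd": cal.oxd_from_ratio(m.ratio, calib) if np.isfinite(m.ratio) else np.nan,
                "mecp2_positive": None,
                "included": True,
                "exclusion_reason": None,
            }
        )
    return pd.DataFrame(rows, columns=list(stats.NEURON_COLUMNS))


def recover_group_mean(
    oxd_mean: float,
    oxd_sd: float,
    n_cells: int,
    calib: cal.CalibrationParams = cal.DEFAULT_CALIBRATION,
    seed: int = 0,
    scenario: synthdata.SimScenario | None = None,
    region: str = "CA1",
    genotype: str = "WT",
    age_group: str = "p50",
) -> float:
    """Recover the cell-level mean OxD of one simulated population.

    Simulates ``n_cells`` neurons with ground-truth OxD ~ truncated
    normal(``oxd_mean``, ``oxd_sd``) spread over as many fields as
    needed, runs image → ratio → OxD → intactness filter → ROUT, and
    returns the mean OxD over the included cells.
    """
    base = scenario or synthdata.SimScenario()
    import dataclasses

    base = dataclasses.replace(
        base, group_oxd={(region, genotype, age_group): (oxd_mean, oxd_sd)}
    )
    model = synthdata.make_fluorophore_model(calib)
    n_fields = int(np.ceil(n_cells / base.cells_per_field))
    field_seeds = _seeds(seed, n_fields)
    frames = []
    remaining = n_cells
    for i in range(n_fields):
        n = min(base.cells_per_field, remaining)
        remaining -= n
        field, _ = synthdata.simulate_field(
            base,
            model,
            slice_id=f"s{i // 4}",
            region=region,
            genotype=genotype,
            age_group=age_group,
            seed=field_seeds[i],
            field_id=f"f{i}",
            n_cells=n,
        )
        meas = quantify_field(field)
        frames.append(_measurements_to_cells(meas, field.metadata, calib))
    cells = pd.concat(frames, ignore_index=True)
    cells = stats.filter_intact(cells)
    cells = stats.apply_rout(cells)
    summary = stats.aggregate(cells, level="cell")
    return float(summary["mean"].iloc[0])


def recover_slice_level(
    slice_mean: float,
    slice_sd: float,
    n_slices: int,
    cells_per_slice: int = 30,
    within_slice_sd: float = 0.10,
    calib: cal.CalibrationParams = cal.DEFAULT_CALIBRATION,
    seed: int = 0,
    scenario: synthdata.SimScenario | None = None,
    region: str = "DG",
    genotype: str = "WT",
    age_group: str = "gt_p100",
) -> float:
    """Recover a slice-level group mean (slice-first aggregation).

    Per-slice true mean OxD values are drawn from
    normal(``slice_mean``, ``slice_sd``); each slice contributes
    ``cells_per_slice`` neurons spread around its own mean with
    ``within_slice_sd``.  The pipeline aggregates neurons to per-slice
    means first, then averages the slices.
    """
    base = scenario or synthdata.SimScenario()
    import dataclasses

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    slice_means = np.clip(
        rng.normal(slice_mean, slice_sd, n_slices), 0.05, 0.95
    )
    model = synthdata.make_fluorophore_model(calib)
    fields_per_slice = int(np.ceil(cells_per_slice / base.cells_per_field))
    seeds = _seeds(seed + 1, n_slices * fields_per_slice)
    frames = []
    for s in range(n_slices):
        sc = dataclasses.replace(
            base,
            group_oxd={(region, genotype, age_group): (float(slice_means[s]), within_slice_sd)},
        )
        remaining = cells_per_slice
        for f in range(fields_per_slice):
            n = min(base.cells_per_field, remaining)
            remaining -= n
            field, _ = synthdata.simulate_field(
                sc,
                model,
                slice_id=f"s{s}",
                region=region,
                genotype=genotype,
                age_group=age_group,
                seed=seeds[s * fields_per_slice + f],
                field_id=f"f{f}",
                n_cells=n,
            )
            meas = quantify_field(field)
            frames.append(_measurements_to_cells(meas, field.metadata, calib))
    cells = pd.concat(frames, ignore_index=True)
    cells = stats.filter_intact(cells)
    cells = stats.apply_rout(cells)
    summary = stats.aggregate(cells, level="slice")
    return float(summary["mean"].iloc[0])


def recover_correlative(
    n_deficient_total: int = 193,
    n_positive_total: int = 110,
    effect: float = 1.101,
    n_slices: int = 6,
    seed: int = 0,
    scenario: synthdata.SimScenario | None = None,
) -> tuple[float, stats.WelchResult, pd.DataFrame]:
    """Run the full correlative stage on simulated mosaic slices.

    Per slice: simulate the live/fixed pair, register by fiducials,
    detect live somata and measure their ratios, classify fixed-field
    nuclei from the immunolabel channel, match live cells to nuclei, and
    pool the matched, classified ratios across slices for per-slice
    normalisation and the Welch comparison.

    Returns (pooled deficient-class mean normalised ratio, Welch result,
    normalised table).
    """
    scenario = scenario or synthdata.SimScenario(image_shape=(360, 360))
    per_def = _split_counts(n_deficient_total, n_slices)
    per_pos = _split_counts(n_positive_total, n_slices)
    slice_seeds = _seeds(seed, n_slices)
    frames = []
    for s in range(n_slices):
        live, fixed, _ = synthdata.simulate_correlative_slice(
            n_deficient=per_def[s],
            n_positive=per_pos[s],
            effect=effect,
            scenario=scenario,
            slice_id=f"s{s}",
            seed=slice_seeds[s],
        )
        offset = correlative.register_by_fiducials(live, fixed)
        live_sub = ratiometric.subtract_background(live)
        ratio = ratiometric.compute_ratio_image(live_sub)
        rois = ratiometric.detect_somata(live_sub)
        meas = ratiometric.measure_rois(
            live_sub, ratio, ratiometric.shrink_rois(rois, factor=0.75)
        )
        meas_by_id = {m.cell_id: m for m in meas}
        with np.errstate(all="ignore"):
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                calls = correlative.classify_mecp2(fixed)
        matches = correlative.match_cells(
            rois, calls, offset=offset, matching_radius=scenario.soma_radius
        )
        call_by_id = {c.nucleus_id: c for c in calls}
        for _, row in matches[matches["matched"]].iterrows():
            m = meas_by_id[row["cell_id"]]
            if not np.isfinite(m.ratio):
                continue
            frames.append(
                {
                    "cell_id": f"s{s}_{row['cell_id']}",
                    "slice_id": f"s{s}",
                    "ratio": m.ratio,
                    "mecp2_positive": call_by_id[row["nucleus_id"]].positive,
                }
            )
    cells = pd.DataFrame(frames)
    norm, comparison = correlative.normalize_and_compare(cells)
    deficient_mean = float(
        norm.loc[~norm["mecp2_positive"].astype(bool), "ratio_norm"].mean()
    )
    return deficient_mean, comparison, norm


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    counts = [base] * parts
    for i in range(total - base * parts):
        counts[i] += 1
    return counts
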