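"""Correlative redox microscopy: re-identify live-imaged neurons after
fixation and relate their redox state to MeCP2 expression.

The live ratiometric recording and the post-fixation immunofluorescence
recording of the same field are registered by the bleach-mark fiducials
burnt into the tissue next to the imaged region; nuclei are classified
as MeCP2-positive or MeCP2-deficient from the immunolabel channel; live
somata are matched one-to-one to fixed-field nuclei; and the redox
ratios of the two classes are compared after per-slice normalisation to
the MeCP2-positive mean.  Because the fixed recording uses different
optics and filters than the calibration recordings, the comparison runs
on raw F740/F910 ratios, not OxD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial import cKDTree
from skimage import filters

from .ratiometric import CircularRoi, FieldImage, detect_somata
from .stats import WelchResult, welch_t

__all__ = [
    "MecP2Call",
    "RegistrationError",
    "classify_mecp2",
    "match_cells",
    "normalize_and_compare",
    "percent_positive",
    "register_by_fiducials",
]


class RegistrationError(RuntimeError):
    """Fiducial-based registration failed or is unreliable."""


def _fiducial_mask(field: FieldImage, channel: str) -> np.ndarray:
    """Binarise bleach-mark footprints: pixels far darker than the tissue.

    The bleached square sits at background level while the surrounding
    tissue carries diffuse fluorescence, so a threshold at half the
    median intensity isolates the mark.
    """
    img = np.asarray(field.channel(channel), dtype=float)
    return img < 0.5 * np.median(img)


def register_by_fiducials(
    live_field: FieldImage,
    fixed_field: FieldImage,
    search_radius: int = 20,
    live_channel: str = "F910",
    fixed_channel: str = "structural",
    min_confidence: float = 0.5,
) -> tuple[int, int]:
    """Estimate the (dx, dy) translation live -> fixed from bleach marks.

    Maximises the cross-correlation of the binarised fiducial masks over
    displacements within ``search_radius`` pixels; exact to 1 px for
    synthetic integer shifts.  The confidence is the mask overlap at the
    peak relative to the smaller mask; below ``min_confidence`` a
    :class:`RegistrationError` is raised, as it is when either field
    shows no fiducial footprint at all.
    """
    live_mask = _fiducial_mask(live_field, live_channel).astype(float)
    fixed_mask = _fiducial_mask(fixed_field, fixed_channel).astype(float)
    if live_mask.sum() == 0 or fixed_mask.sum() == 0:
        raise RegistrationError("no fiducial footprint detected")
    corr = signal.fftconvolve(fixed_mask, live_mask[::-1, ::-1], mode="full")
    h, w = live_mask.shape
    # displacement d such that fixed(p) ~ live(p - d)
    cy, cx = h - 1, w - 1
    y0, y1 = cy - search_radius, cy + search_radius + 1
    x0, x1 = cx - search_radius, cx + search_radius + 1
    window = corr[max(0, y0) : y1, max(0, x0) : x1]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    dy = iy + max(0, y0) - cy
    dx = ix + max(0, x0) - cx
    confidence = window[iy, ix] / min(live_mask.sum(), fixed_mask.sum())
    if confidence < min_confidence:
        raise RegistrationError(
            f"registration confidence {confidence:.2f} below {min_confidence}"
        )
    return int(dx), int(dy)


def _split_log_intensities(scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Two-class split of 1-D log intensities with a bimodality diagnostic.

    Fits one- and two-component Gaussian mixtures; the diagnostic is the
    BIC improvement of the two-component model (ΔBIC = BIC1 - BIC2,
    values above ~10 are strong evidence of two expression classes).
    The class boundary falls back to the Otsu threshold when the mixture
    fit degenerates.
    """
    if np.ptp(scores) == 0:
        return np.zeros(len(scores), dtype=bool), -np.inf
    try:
        from sklearn.mixture import GaussianMixture

        x = scores.reshape(-1, 1)
        gmm2 = GaussianMixture(n_components=2, n_init=3, random_state=0).fit(x)
        gmm1 = GaussianMixture(n_components=1, random_state=0).fit(x)
        delta_bic = float(gmm1.bic(x) - gmm2.bic(x))
        labels = gmm2.predict(x)
        positive = labels == int(np.argmax(gmm2.means_.ravel()))
        if positive.all() or (~positive).all():
            raise RuntimeError("degenerate mixture split")
    except Exception:  # noqa: BLE001 - any fit failure falls back to Otsu
        thr = float(filters.threshold_otsu(scores))
        positive = scores > thr
        delta_bic = -np.inf
    return positive, delta_bic


@dataclass(frozen=True)
class MecP2Call:
    """Per-nucleus MeCP2 classification with its intensity score."""

    nucleus_id: str
    x: float
    y: float
    positive: bool
    log_intensity: float


def classify_mecp2(
    fixed_field: FieldImage,
    nuclei_rois: Sequence[CircularRoi] | None = None,
    nuclear_channel: str = "nuclear",
    label_channel: str = "immunolabel",
) -> list[MecP2Call]:
    """Classify nuclei as MeCP2-positive from the immunolabel channel.

    Nuclear masks come from ``nuclei_rois`` (detected on the nuclear
    channel when not supplied); each nucleus is scored by its mean
    log immunolabel intensity and the population is split in two by a
    two-component Gaussian mixture on the log scores (Otsu threshold as
    fallback).  A weak bimodality diagnostic — the BIC improvement of
    the two-component over the one-component fit below 10 — triggers a
    warning (the split is then unreliable, e.g. when all nuclei share
    one expression status), but a classification is still returned.
    """
    if nuclei_rois is None:
        nuclei_rois = detect_somata(
            fixed_field, min_radius=1.5, max_radius=12.0, channel=nuclear_channel
        )
    if len(nuclei_rois) < 4:
        raise ValueError("need at least 4 nuclei for classification")
    label = np.asarray(fixed_field.channel(label_channel), dtype=float)
    h, w = label.shape
    scores = []
    for roi in nuclei_rois:
        yy, xx = np.ogrid[:h, :w]
        mask = (xx - roi.x) ** 2 + (yy - roi.y) ** 2 <= roi.radius**2
        scores.append(np.log(max(label[mask].mean(), 1e-9)))
    scores = np.asarray(scores)
    positive, delta_bic = _split_log_intensities(scores)
    if delta_bic < 10.0:
        warnings.warn(
            "immunolabel intensity distribution weakly bimodal "
            f"(two-component ΔBIC = {delta_bic:.1f}); MeCP2 classification "
            "may be unreliable",
            stacklevel=2,
        )
    return [
        MecP2Call(
            nucleus_id=f"nuc{i:04d}",
            x=roi.x,
            y=roi.y,
            positive=bool(pos),
            log_intensity=float(s),
        )
        for i, (roi, pos, s) in enumerate(zip(nuclei_rois, positive, scores))
    ]


def match_cells(
    live_rois: Sequence[CircularRoi],
    fixed_nuclei: Sequence[MecP2Call] | Sequence[CircularRoi],
    offset: tuple[float, float] = (0.0, 0.0),
    matching_radius: float = 6.0,
) -> pd.DataFrame:
    """Greedy one-to-one nearest-neighbour matching of live somata to
    fixed-field nuclei after applying the registration offset.

    Returns a table with one row per live ROI: ``cell_id``,
    ``nucleus_id`` (None when unmatched), ``distance`` and ``matched``.
    Pairs are claimed in order of ascending distance, so each nucleus is
    used at most once.
    """
    dx, dy = offset
    rows = [
        {"cell_id": r.cell_id, "nucleus_id": None, "distance": np.nan, "matched": False}
        for r in live_rois
    ]
    if not live_rois or not fixed_nuclei:
        return pd.DataFrame(rows)
    live_pts = np.array([[r.x + dx, r.y + dy] for r in live_rois])
    fixed_pts = np.array([[n.x, n.y] for n in fixed_nuclei])
    nuc_ids = [getattr(n, "nucleus_id", getattr(n, "cell_id", str(i))) for i, n in enumerate(fixed_nuclei)]
    tree = cKDTree(fixed_pts)
    k = min(4, len(fixed_pts))
    dists, idxs = tree.query(live_pts, k=k)
    dists = np.atleast_2d(dists.reshape(len(live_pts), -1))
    idxs = np.atleast_2d(idxs.reshape(len(live_pts), -1))
    pairs = []
    for i in range(len(live_pts)):
        for dist, j in zip(dists[i], idxs[i]):
            if np.isfinite(dist) and dist <= matching_radius:
                pairs.append((float(dist), i, int(j)))
    pairs.sort()
    used_live: set[int] = set()
    used_fixed: set[int] = set()
    for dist, i, j in pairs:
        if i in used_live or j in used_fixed:
            continue
        used_live.add(i)
        used_fixed.add(j)
        rows[i] = {
            "cell_id": live_rois[i].cell_id,
            "nucleus_id": nuc_ids[j],
            "distance": dist,
            "matched": True,
        }
    return pd.DataFrame(rows)


def percent_positive(n_positive: int, n_total: int) -> float:
    """MeCP2-positive percentage of a re-identified neuron population."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_positive / n_total


def normalize_and_compare(
    cells: pd.DataFrame,
    min_positive: int = 5,
    denominator: str = "inclusive",
) -> tuple[pd.DataFrame, WelchResult]:
    """Per-slice normalisation to the MeCP2-positive mean, then Welch.

    ``cells`` needs columns ``cell_id``, ``slice_id``, ``ratio`` and
    ``mecp2_positive``.  Every cell's ratio is divided by its own
    slice's mean ratio over MeCP2-positive cells (``denominator =
    "inclusive"``: each positive cell's own value enters the mean;
    ``"leave_one_out"``: a positive cell is normalised by the mean of
    the *other* positive cells).  Slices with fewer than ``min_positive``
    positive cells are excluded.  Returns the normalised table and the
    Welch's t-test of deficient vs positive pooled across slices.
    """
    if denominator not in ("inclusive", "leave_one_out"):
        raise ValueError("denominator must be 'inclusive' or 'leave_one_out'")
    frames = []
    for slice_id, g in cells.groupby("slice_id"):
        pos = g[g["mecp2_positive"].astype(bool)]
        n_pos = len(pos)
        if n_pos < min_positive:
            continue
        pos_sum = pos["ratio"].sum()
        out = g.copy()
        if denominator == "inclusive":
            out["ratio_norm"] = g["ratio"] / (pos_sum / n_pos)
        else:
            denom = np.where(
                g["mecp2_positive"].astype(bool) & (n_pos > 1),
                (pos_sum - g["ratio"]) / (n_pos - 1),
                pos_sum / n_pos,
            )
            out["ratio_norm"] = g["ratio"] / denom
        frames.append(out)
    if not frames:
        raise ValueError("no slice satisfies the minimum positive-cell count")
    norm = pd.concat(frames, ignore_index=True)
    deficient = norm.loc[~norm["mecp2_positive"].astype(bool), "ratio_norm"]
    positive = norm.loc[norm["mecp2_positive"].astype(bool), "ratio_norm"]
    try:
        comparison = welch_t(deficient, positive)
    except ValueError as exc:
        # degenerate class (n < 2 or zero variance): the normalised table
        # is still meaningful, the test is not
        warnings.warn(f"Welch comparison not computed: {exc}", stacklevel=2)
        comparison = None
    return norm, comparison
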