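"""Peptide-microarray quantification.

Stages, mirroring the scanner-image analysis of the method: (1) locate the
a-priori-known GAL grid in the image, which may be rotated or shifted, by
maximizing template correlation over (rotation, dx, dy); (2) segment each
spot with a seeding threshold and a masking threshold combined by geodesic
dilation (morphological reconstruction); (3) score each spot as the sum of
its segment pixels after subtracting the per-pixel median of the block
background; (4) filter each quadruple of replicate spots by Tukey fences
(1.5 x IQR beyond the quartiles); (5) express each peptide's signal as a
multiple of the water (buffer-only) control signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates, spline_filter
from scipy.optimize import minimize

from .gal import ArrayLayout, Block


class GridNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class GridTransform:
    """Rigid transform of the nominal grid: rotate about the image center
    (degrees, counter-clockwise in (x, y)), then translate by (dx, dy) px."""

    rotation: float = 0.0
    dx: float = 0.0
    dy: float = 0.0


def transform_centers(
    centers: np.ndarray, transform: GridTransform, image_shape: tuple[int, int]
) -> np.ndarray:
    """Apply a GridTransform to (n, 2) nominal (x, y) spot centers.

    The rotation pivot is the image center; the same convention is used by
    the simulator and the grid detector.
    """
    h, w = image_shape
    pivot = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    th = np.deg2rad(transform.rotation)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = (centers - pivot) @ rot.T + pivot
    out[:, 0] += transform.dx
    out[:, 1] += transform.dy
    return out


# ---------------------------------------------------------------------------
# grid detection


def _sample(smooth: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear image samples at (x, y) points (points outside -> 0)."""
    coords = np.vstack([pts[..., 1].ravel(), pts[..., 0].ravel()])
    return map_coordinates(smooth, coords, order=1, mode="constant", cval=0.0)


def detect_grid(
    image: np.ndarray,
    layout: ArrayLayout,
    max_rotation: float = 2.0,
    max_shift: float = 8.0,
    rotation_step: float = 0.25,
    shift_step: float = 1.0,
    smooth_sigma: float = 2.0,
    floor_contrast: float = 0.02,
) -> GridTransform:
    """Recover the grid's rotation and shift by template correlation.

    The image is Gaussian-smoothed and the mean intensity at the
    transformed nominal spot centers is maximized: a coarse grid search
    over (rotation, dx, dy) followed by Nelder-Mead refinement. Raises
    GridNotFoundError when the best pose does not stand out from the pose
    population — (best - median) / median below ``floor_contrast`` — as on
    a blank image where every candidate pose scores alike.
    """
    img = np.asarray(image, dtype=float)
    smooth = gaussian_filter(img, smooth_sigma)
    centers = layout.centers()
    h, w = img.shape
    pivot = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    rots = np.arange(-max_rotation, max_rotation + 1e-9, rotation_step)
    shifts = np.arange(-max_shift, max_shift + 1e-9, shift_step)
    ddx, ddy = np.meshgrid(shifts, shifts, indexing="ij")
    offsets = np.stack([ddx.ravel(), ddy.ravel()], axis=1)  # (m, 2)

    best_score, best = -np.inf, (0.0, 0.0, 0.0)
    rel = centers - pivot
    all_scores = []
    for r in rots:
        th = np.deg2rad(r)
        rotm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        base = rel @ rotm.T + pivot  # (n, 2)
        pts = base[None, :, :] + offsets[:, None, :]  # (m, n, 2)
        vals = _sample(smooth, pts).reshape(len(offsets), len(centers))
        scores = vals.mean(axis=1)
        all_scores.append(scores)
        i = int(np.argmax(scores))
        if scores[i] > best_score:
            best_score = scores[i]
            best = (float(r), float(offsets[i, 0]), float(offsets[i, 1]))

    pool = np.concatenate(all_scores)
    med = float(np.median(pool))
    contrast = (best_score - med) / max(abs(med), 1.0)
    if contrast < floor_contrast:
        raise GridNotFoundError(
            f"grid not found: best pose contrast {contrast:.4f} "
            f"below floor {floor_contrast:.4f}"
        )

    # cubic-spline sampling for the sub-pixel refinement stage
    coeffs = spline_filter(smooth, order=3)

    def neg_score(x):
        tr = GridTransform(*x)
        pts = transform_centers(centers, tr, img.shape)
        coords = np.vstack([pts[:, 1], pts[:, 0]])
        vals = map_coordinates(
            coeffs, coords, order=3, prefilter=False, mode="constant", cval=0.0
        )
        return -float(vals.mean())

    res = minimize(
        neg_score,
        x0=np.array(best),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 600},
    )
    return GridTransform(
        rotation=float(res.x[0]), dx=float(res.x[1]), dy=float(res.x[2])
    )


# ---------------------------------------------------------------------------
# segmentation: dual threshold + geodesic dilation


def geodesic_segment(
    window: np.ndarray,
    seed_thresh: float,
    mask_thresh: float,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Binary morphological reconstruction of seeds under a mask.

    seeds = window > seed_thresh, mask = window > mask_thresh; the segment
    is the 4-connected geodesic dilation of the seeds constrained by the
    mask, iterated to fixpoint. ``valid`` optionally restricts the domain
    (e.g. to a disk window).
    """
    if mask_thresh > seed_thresh:
        raise ValueError("mask_thresh must be <= seed_thresh")
    w = np.asarray(window, dtype=float)
    mask = w > mask_thresh
    if valid is not None:
        mask &= valid
    seg = (w > seed_thresh) & mask
    if not seg.any():
        return np.zeros_like(mask)
    while True:
        grown = seg.copy()
        grown[1:, :] |= seg[:-1, :]
        grown[:-1, :] |= seg[1:, :]
        grown[:, 1:] |= seg[:, :-1]
        grown[:, :-1] |= seg[:, 1:]
        grown &= mask
        if (grown == seg).all():
            return seg
        seg = grown


@dataclass
class SpotMask:
    """Segment of one spot: boolean mask over a window bounding box."""

    row0: int
    col0: int
    mask: np.ndarray  # bool, shape of the bbox
    empty: bool

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def pixel_indices(self) -> tuple[np.ndarray, np.ndarray]:
        r, c = np.nonzero(self.mask)
        return r + self.row0, c + self.col0


def segment_spot(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    seed_thresh: float,
    mask_thresh: float,
) -> SpotMask:
    """Segment one spot inside a disk search window around its center.

    ``center`` is (x, y) in pixels. Returns the reconstructed segment; an
    empty segment (no pixel above the seeding threshold) is flagged.
    """
    x, y = center
    h, w = image.shape
    r0 = max(0, int(np.floor(y - radius)))
    r1 = min(h, int(np.ceil(y + radius)) + 1)
    c0 = max(0, int(np.floor(x - radius)))
    c1 = min(w, int(np.ceil(x + radius)) + 1)
    if r0 >= r1 or c0 >= c1:
        return SpotMask(r0, c0, np.zeros((0, 0), dtype=bool), empty=True)
    win = np.asarray(image[r0:r1, c0:c1], dtype=float)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    valid = (cc - x) ** 2 + (rr - y) ** 2 <= radius ** 2
    seg = geodesic_segment(win, seed_thresh, mask_thresh, valid=valid)
    return SpotMask(r0, c0, seg, empty=not seg.any())


# ---------------------------------------------------------------------------
# backgrounds and totals


def block_background(
    image: np.ndarray,
    layout: ArrayLayout,
    block: Block | int,
    transform: GridTransform,
    bg_exclusion_factor: float = 2.0,
    margin: float = 0.5,
) -> tuple[float, float]:
    """Per-pixel background of one block: (median, robust SD).

    Background pixels are those inside the block's (transformed) bounding
    box but outside every spot's exclusion disk (spot radius multiplied by
    ``bg_exclusion_factor``). The robust SD (1.4826 x MAD) feeds the
    default seeding/masking thresholds.
    """
    if isinstance(block, int):
        block = layout.blocks[block - 1]
    sel = layout.spots["block"] == block.index
    centers = transform_centers(
        layout.centers()[sel.to_numpy()], transform, image.shape
    )
    r_ex = layout.spot_radius * bg_exclusion_factor
    pad = block.col_spacing * margin
    x0 = max(0, int(np.floor(centers[:, 0].min() - pad)))
    x1 = min(image.shape[1], int(np.ceil(centers[:, 0].max() + pad)) + 1)
    y0 = max(0, int(np.floor(centers[:, 1].min() - pad)))
    y1 = min(image.shape[0], int(np.ceil(centers[:, 1].max() + pad)) + 1)
    rr, cc = np.mgrid[y0:y1, x0:x1]
    keep = np.ones(rr.shape, dtype=bool)
    for cx, cy in centers:
        keep &= (cc - cx) ** 2 + (rr - cy) ** 2 > r_ex ** 2
    if not keep.any():
        raise ValueError(f"block {block.index} has no non-spot background pixels")
    px = np.asarray(image, dtype=float)[y0:y1, x0:x1][keep]
    med = float(np.median(px))
    mad = float(np.median(np.abs(px - med)))
    return med, 1.4826 * mad


@dataclass
class SpotMeasurement:
    spot_index: int
    spot_id: str
    block: int
    n_pixels: int
    raw_total: float
    bg_median: float
    corrected_total: float
    empty_segment: bool = False
    saturated: bool = False
    clamped: bool = False


def spot_total(
    image: np.ndarray,
    spot_mask: SpotMask,
    bg_median: float,
    spot_index: int = -1,
    spot_id: str = "",
    block: int = 0,
    saturation: float = 65535,
) -> SpotMeasurement:
    """Background-corrected total intensity of one segmented spot.

    corrected = sum over segment pixels of (pixel - block bg median);
    a negative sum is clamped to zero and flagged.
    """
    if spot_mask.empty or spot_mask.n_pixels == 0:
        return SpotMeasurement(
            spot_index, spot_id, block, 0, 0.0, bg_median, 0.0, empty_segment=True
        )
    r, c = spot_mask.pixel_indices()
    px = np.asarray(image, dtype=float)[r, c]
    raw = float(px.sum())
    corrected = raw - bg_median * len(px)
    clamped = corrected < 0
    return SpotMeasurement(
        spot_index=spot_index,
        spot_id=spot_id,
        block=block,
        n_pixels=len(px),
        raw_total=raw,
        bg_median=bg_median,
        corrected_total=max(0.0, corrected),
        saturated=bool((px >= saturation).any()),
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# replicate filtering and normalization


def iqr_filter(values) -> list[float]:
    """Tukey-fence filter of a replicate quadruple.

    Q1/Q3 by linear interpolation on the sorted values (positions
    1 + 0.25(n-1) and 1 + 0.75(n-1)); values outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (exclusive) are dropped.
    """
    v = np.asarray(values, dtype=float)
    if v.size != 4:
        raise ValueError(f"expected a quadruple, got {v.size} values")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [float(x) for x in v if lo <= x <= hi]


@dataclass
class ReplicateSummary:
    peptide_id: str
    corrected_totals: tuple[float, ...]
    retained: tuple[float, ...]
    adjusted: float  # fold over the water baseline
    positive: bool


def water_baseline(water_quadruples: list[list[float]]) -> float:
    """Water signal: median of all water corrected totals, each quadruple
    first passed through the same Tukey-fence filter."""
    retained: list[float] = []
    for quad in water_quadruples:
        retained.extend(iqr_filter(quad))
    if not retained:
        raise ValueError("invalid water baseline: no retained water spots")
    return float(np.median(retained))


def normalize_and_call(
    retained: list[float],
    water_median: float,
    peptide_id: str = "",
    corrected_totals: tuple[float, ...] = (),
    pos_fold: float = 3.0,
) -> ReplicateSummary:
    """Adjusted intensity = median(retained) / water median; positive when
    the fold reaches pos_fold."""
    if water_median <= 0:
        raise ValueError("invalid water baseline")
    adjusted = float(np.median(retained)) / water_median if retained else 0.0
    return ReplicateSummary(
        peptide_id=peptide_id,
        corrected_totals=tuple(corrected_totals),
        retained=tuple(retained),
        adjusted=adjusted,
        positive=adjusted >= pos_fold,
    )


# ---------------------------------------------------------------------------
# full-image pipeline


@dataclass
class ArrayQuantResult:
    transform: GridTransform
    spots: pd.DataFrame      # per-spot GPR-like table
    summaries: pd.DataFrame  # per-peptide adjusted folds
    water_median: float
    block_background: dict[int, tuple[float, float]] = field(default_factory=dict)

    def write_tsv(self, spots_path: str | os.PathLike, summary_path: str | os.PathLike):
        self.spots.to_csv(spots_path, sep="\t", index=False)
        self.summaries.to_csv(summary_path, sep="\t", index=False)


def quantify_image(
    image: np.ndarray,
    layout: ArrayLayout,
    transform: GridTransform | None = None,
    seed_thresh: float | None = None,
    mask_thresh: float | None = None,
    seed_sigmas: float = 6.0,
    mask_sigmas: float = 3.0,
    window_factor: float = 1.6,
    bg_exclusion_factor: float = 2.0,
    pos_fold: float = 3.0,
    max_rotation: float = 2.0,
    max_shift: float = 8.0,
) -> ArrayQuantResult:
    """Run the full quantification pipeline on one scan image.

    When thresholds are not given they default per block to
    bg_median + seed_sigmas * bg_sd (seeding) and + mask_sigmas * bg_sd
    (masking), from the block background's robust statistics.
    """
    if transform is None:
        transform = detect_grid(
            image, layout, max_rotation=max_rotation, max_shift=max_shift
        )
    centers = transform_centers(layout.centers(), transform, image.shape)
    radius = layout.spot_radius * window_factor

    bg: dict[int, tuple[float, float]] = {}
    for b in layout.blocks:
        bg[b.index] = block_background(
            image, layout, b, transform, bg_exclusion_factor=bg_exclusion_factor
        )

    measurements = []
    for idx in layout.spots.index:
        b = int(layout.spots.loc[idx, "block"])
        med, sd = bg[b]
        st = seed_thresh if seed_thresh is not None else med + seed_sigmas * sd
        mt = mask_thresh if mask_thresh is not None else med + mask_sigmas * sd
        mask = segment_spot(image, tuple(centers[idx]), radius, st, mt)
        measurements.append(
            spot_total(
                image, mask, med,
                spot_index=idx,
                spot_id=str(layout.spots.loc[idx, "id"]),
                block=b,
            )
        )
    spots_df = pd.DataFrame(
        {
            "spot_index": [m.spot_index for m in measurements],
            "id": [m.spot_id for m in measurements],
            "block": [m.block for m in measurements],
            "row": layout.spots["row"].to_numpy(),
            "column": layout.spots["column"].to_numpy(),
            "n_pixels": [m.n_pixels for m in measurements],
            "raw_total": [m.raw_total for m in measurements],
            "bg_median": [m.bg_median for m in measurements],
            "corrected_total": [m.corrected_total for m in measurements],
            "empty_segment": [m.empty_segment for m in measurements],
            "saturated": [m.saturated for m in measurements],
        }
    )
    by_index = {m.spot_index: m for m in measurements}

    water_quads = []
    water = layout.water_spots()
    for i in range(0, len(water), 4):
        quad = water[i:i + 4]
        if len(quad) == 4:
            water_quads.append([by_index[j].corrected_total for j in quad])
    wmed = water_baseline(water_quads)

    rows = []
    for pid, members in layout.replicate_groups().items():
        totals = [by_index[j].corrected_total for j in members]
        retained = iqr_filter(totals)
        summ = normalize_and_call(
            retained, wmed, peptide_id=pid, corrected_totals=tuple(totals),
            pos_fold=pos_fold,
        )
        rows.append(
            {
                "id": pid,
                "n_retained": len(retained),
                "median_corrected": float(np.median(retained)) if retained else 0.0,
                "adjusted": summ.adjusted,
                "positive": summ.positive,
            }
        )
    summaries = pd.DataFrame(rows).sort_values("id", kind="stable").reset_index(drop=True)
    return ArrayQuantResult(
        transform=transform,
        spots=spots_df,
        summaries=summaries,
        water_median=wmed,
        block_background=bg,
    )
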