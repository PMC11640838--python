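"""Synthetic 16-bit array scans with known spot intensities and grid pose.

Spots are rendered as flat-top disks with a Gaussian edge falloff on a
per-block additive background, optionally with Gaussian read noise, a few
outlier spots at a distinct intensity, and a small rigid transform
(rotation + shift) of the whole grid. The generator records *realized*
per-spot totals — the sum of the quantized, pre-noise flux over each
spot's compact support — so noiseless scans admit exact downstream checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .arrayquant import GridTransform, transform_centers
from .gal import ArrayLayout, image_shape_for

EDGE_SIGMA = 1.0          # px, Gaussian falloff of the spot edge
FLAT_SHRINK = 2.0         # flat top radius = spot radius - FLAT_SHRINK
SUPPORT_BEYOND = 2.0      # support radius = spot radius + SUPPORT_BEYOND


@dataclass
class ImageTruth:
    """Ground truth of one rendered scan.

    ``spot_table`` has one row per spot: requested analog total,
    realized (quantized, pre-noise) total, outlier flag, center after the
    transform. Background levels are integers per block so the noiseless
    corrected totals are exact.
    """

    transform: GridTransform
    background_level: dict[int, int]
    noise_sd: float
    spot_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def outlier_spot_ids(self) -> list[int]:
        return list(self.spot_table.index[self.spot_table["outlier"]])

    def group_fold_truth(self, layout: ArrayLayout) -> pd.DataFrame:
        """Per-peptide truth folds over water, replicating the pipeline's
        summarization (Tukey-fence filter, medians) on realized totals."""
        from .arrayquant import iqr_filter, water_baseline

        water = layout.water_spots()
        quads = [
            list(self.spot_table.loc[water[i:i + 4], "realized_total"])
            for i in range(0, len(water), 4)
        ]
        wmed = water_baseline(quads)
        rows = []
        for pid, members in layout.replicate_groups().items():
            retained = iqr_filter(
                list(self.spot_table.loc[members, "realized_total"])
            )
            rows.append(
                {"id": pid, "true_fold": float(np.median(retained)) / wmed}
            )
        return (
            pd.DataFrame(rows).sort_values("id", kind="stable").reset_index(drop=True)
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.spot_table.to_csv(path, sep="\t", index=True, index_label="spot_index")


def _spot_profile(shape, cx, cy, radius):
    """Unit-amplitude flat-top disk with Gaussian edge, compact support."""
    r_flat = max(radius - FLAT_SHRINK, 1.0)
    r_sup = radius + SUPPORT_BEYOND
    y0, y1 = int(np.floor(cy - r_sup)), int(np.ceil(cy + r_sup)) + 1
    x0, x1 = int(np.floor(cx - r_sup)), int(np.ceil(cx + r_sup)) + 1
    if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
        raise ValueError("transform pushes a spot out of frame")
    rr, cc = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((cc - cx) ** 2 + (rr - cy) ** 2)
    prof = np.where(
        d <= r_flat, 1.0, np.exp(-((d - r_flat) ** 2) / (2 * EDGE_SIGMA ** 2))
    )
    prof[d > r_sup] = 0.0
    return (slice(y0, y1), slice(x0, x1)), prof


def gen_array_image(
    layout: ArrayLayout,
    group_intensities: dict[str, float],
    seed: int,
    transform: GridTransform = GridTransform(),
    background_levels: dict[int, int] | None = None,
    noise_sd: float = 0.0,
    outlier_fraction: float = 0.05,
    outlier_factor: float = 8.0,
    replicate_cv: float = 0.0,
    image_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, ImageTruth]:
    """Render one scan image plus its truth record.

    ``group_intensities`` gives the requested total flux per replicate
    group id (including ``water``); every spot of the group is rendered at
    that total (times an optional log-normal replicate scatter of CV
    ``replicate_cv``). A random ``outlier_fraction`` of peptide spots is
    rendered at ``outlier_factor`` times its group total instead.
    """
    rng = np.random.default_rng(seed)
    shape = image_shape or image_shape_for(layout)
    if background_levels is None:
        background_levels = {
            b.index: int(200 + 100 * rng.integers(0, 3)) for b in layout.blocks
        }
    flux = np.zeros(shape, dtype=float)
    centers = transform_centers(layout.centers(), transform, shape)
    radius = layout.spot_radius

    n_spots = len(layout.spots)
    requested = np.zeros(n_spots)
    outlier = np.zeros(n_spots, dtype=bool)
    groups = dict(layout.replicate_groups())
    groups["water"] = layout.water_spots()
    for pid, members in groups.items():
        if pid not in group_intensities:
            raise ValueError(f"no intensity given for group {pid!r}")
        base = float(group_intensities[pid])
        for j in members:
            scale = (
                rng.lognormal(0.0, replicate_cv) if replicate_cv > 0 else 1.0
            )
            requested[j] = base * scale
    peptide_spots = [
        j for pid, members in groups.items() if pid != "water" for j in members
    ]
    n_out = int(round(outlier_fraction * len(peptide_spots)))
    if n_out:
        picks = rng.choice(peptide_spots, size=n_out, replace=False)
        # at most one outlier per quadruple so the fences can reject it
        seen_groups = set()
        for j in picks:
            gid = layout.spots.loc[j, "id"]
            if gid in seen_groups:
                continue
            seen_groups.add(gid)
            outlier[j] = True
            requested[j] *= outlier_factor

    supports = []
    for j in range(n_spots):
        cx, cy = centers[j]
        sl, prof = _spot_profile(shape, cx, cy, radius)
        amp = requested[j] / prof.sum()
        flux[sl] += amp * prof
        supports.append((sl, prof > 0))

    qflux = np.rint(flux)
    realized = np.array(
        [float(qflux[sl][sup].sum()) for sl, sup in supports]
    )
    img = qflux.copy()
    for b in layout.blocks:
        sel = layout.spots["block"] == b.index
        # background applies to the whole block's bounding region
        bsel = centers[sel.to_numpy()]
        pad = 0.75 * b.col_spacing  # stays clear of the neighbouring block
        y0 = max(0, int(bsel[:, 1].min() - pad))
        y1 = min(shape[0], int(bsel[:, 1].max() + pad) + 1)
        x0 = max(0, int(bsel[:, 0].min() - pad))
        x1 = min(shape[1], int(bsel[:, 0].max() + pad) + 1)
        img[y0:y1, x0:x1] += background_levels[b.index]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    spot_table = pd.DataFrame(
        {
            "id": layout.spots["id"].to_numpy(),
            "block": layout.spots["block"].to_numpy(),
            "requested_total": requested,
            "realized_total": realized,
            "outlier": outlier,
            "center_x": centers[:, 0],
            "center_y": centers[:, 1],
        }
    )
    truth = ImageTruth(
        transform=transform,
        background_level=dict(background_levels),
        noise_sd=noise_sd,
        spot_table=spot_table,
    )
    return img, truth


def write_tiff(image: np.ndarray, path: str | os.PathLike) -> None:
    tifffile.imwrite(path, image.astype(np.uint16))


def read_tiff(path: str | os.PathLike) -> np.ndarray:
    return tifffile.imread(path)
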