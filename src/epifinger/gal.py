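"""GenePix Array List (GAL) layouts: block geometry, spot identities,
replicate quadruples, and water controls.

Coordinates are kept in image pixels throughout (the GAL dialect written
here stores block origins, spacings and spot diameters in the same pixel
units the scan images use), with x = column and y = row of the image
array, 0-based at the top-left pixel center.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

WATER_ID = "water"


@dataclass(frozen=True)
class Block:
    index: int  # 1-based
    origin_x: float
    origin_y: float
    n_cols: int
    n_rows: int
    col_spacing: float
    row_spacing: float
    spot_diameter: float


@dataclass
class ArrayLayout:
    """Array geometry plus per-position spot identities.

    ``spots`` columns: block, row, column (1-based, GAL convention), id,
    name, x, y (nominal center, px). Spots sharing an id form a replicate
    group; the layout is built so each printed peptide appears as a
    quadruple. Water (buffer-only) control spots carry id ``water``.
    """

    blocks: list[Block]
    spots: pd.DataFrame

    def __post_init__(self):
        groups = self.replicate_groups()
        bad = {k: len(v) for k, v in groups.items() if len(v) != 4}
        if bad:
            raise ValueError(f"replicate groups must be quadruples, got {bad}")
        if not (self.spots["id"] == WATER_ID).any():
            raise ValueError("layout has no water control spots")

    def replicate_groups(self) -> dict[str, list[int]]:
        """Peptide id -> list of spot row-indices (water excluded)."""
        out: dict[str, list[int]] = {}
        for idx, sid in zip(self.spots.index, self.spots["id"]):
            if sid != WATER_ID:
                out.setdefault(sid, []).append(idx)
        return out

    def water_spots(self) -> list[int]:
        return list(self.spots.index[self.spots["id"] == WATER_ID])

    def centers(self) -> np.ndarray:
        """Nominal spot centers as an (n, 2) array of (x, y)."""
        return self.spots[["x", "y"]].to_numpy(dtype=float)

    @property
    def spot_radius(self) -> float:
        return self.blocks[0].spot_diameter / 2.0

    def block_of(self, spot_index: int) -> Block:
        return self.blocks[int(self.spots.loc[spot_index, "block"]) - 1]


def make_layout(
    peptide_ids: list[str],
    n_water_groups: int = 2,
    n_blocks: int = 2,
    n_cols: int = 8,
    origin: tuple[float, float] = (30.0, 30.0),
    spacing: float = 22.0,
    block_gap: float = 40.0,
    spot_diameter: float = 10.0,
) -> ArrayLayout:
    """Regular multi-block layout with each id spotted as a quadruple.

    Quadruples are placed as 2x2 mini-squares so replicate spots share
    local background, mirroring printed peptide arrays. Water quadruples
    are appended after the peptides. Blocks are laid out side by side.
    """
    ids = list(peptide_ids) + [WATER_ID] * n_water_groups
    n_groups = len(ids)
    groups_per_block = int(np.ceil(n_groups / n_blocks))
    group_cols = n_cols // 2
    group_rows = int(np.ceil(groups_per_block / group_cols))
    blocks = []
    rows = []
    for b in range(n_blocks):
        ox = origin[0] + b * (group_cols * 2 * spacing + block_gap)
        oy = origin[1]
        blocks.append(
            Block(
                index=b + 1,
                origin_x=ox,
                origin_y=oy,
                n_cols=group_cols * 2,
                n_rows=group_rows * 2,
                col_spacing=spacing,
                row_spacing=spacing,
                spot_diameter=spot_diameter,
            )
        )
    for g, sid in enumerate(ids):
        b = g // groups_per_block
        gi = g % groups_per_block
        gr, gc = divmod(gi, group_cols)
        for dr in (0, 1):
            for dc in (0, 1):
                row = gr * 2 + dr
                col = gc * 2 + dc
                rows.append(
                    {
                        "block": b + 1,
                        "row": row + 1,
                        "column": col + 1,
                        "id": sid,
                        "name": sid,
                        "x": blocks[b].origin_x + col * spacing,
                        "y": blocks[b].origin_y + row * spacing,
                    }
                )
    spots = pd.DataFrame(rows)
    return ArrayLayout(blocks=blocks, spots=spots)


def image_shape_for(layout: ArrayLayout, margin: float = 25.0) -> tuple[int, int]:
    """(n_rows, n_cols) of an image that holds the layout with a margin."""
    c = layout.centers()
    h = int(np.ceil(c[:, 1].max() + layout.spot_radius + margin))
    w = int(np.ceil(c[:, 0].max() + layout.spot_radius + margin))
    return h, w


# ---------------------------------------------------------------------------
# GAL I/O (ATF dialect, GenePix ArrayList V1.0)


def write_gal(layout: ArrayLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        n_header = 2 + len(layout.blocks)
        fh.write("ATF\t1.0\n")
        fh.write(f"{n_header}\t5\n")
        fh.write('"Type=GenePix ArrayList V1.0"\n')
        fh.write(f'"BlockCount={len(layout.blocks)}"\n')
        for b in layout.blocks:
            fh.write(
                f'"Block{b.index}={b.origin_x:g}, {b.origin_y:g}, '
                f"{b.spot_diameter:g}, {b.n_cols}, {b.col_spacing:g}, "
                f'{b.n_rows}, {b.row_spacing:g}"\n'
            )
        fh.write("Block\tRow\tColumn\tID\tName\n")
        for _, s in layout.spots.iterrows():
            fh.write(f"{s['block']}\t{s['row']}\t{s['column']}\t{s['id']}\t{s['name']}\n")


def read_gal(path: str | os.PathLike) -> ArrayLayout:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("ATF"):
        raise ValueError("not an ATF/GAL file")
    n_header = int(lines[1].split("\t")[0])
    header = [ln.strip('"') for ln in lines[2:2 + n_header]]
    blocks = []
    for h in header:
        if h.startswith("Block") and "=" in h and not h.startswith("BlockCount"):
            name, val = h.split("=", 1)
            idx = int(name[5:])
            ox, oy, dia, ncols, csp, nrows, rsp = [
                float(v) for v in val.split(",")
            ]
            blocks.append(
                Block(
                    index=idx,
                    origin_x=ox,
                    origin_y=oy,
                    n_cols=int(ncols),
                    n_rows=int(nrows),
                    col_spacing=csp,
                    row_spacing=rsp,
                    spot_diameter=dia,
                )
            )
    blocks.sort(key=lambda b: b.index)
    cols = lines[2 + n_header].split("\t")
    rows = []
    for ln in lines[3 + n_header:]:
        if not ln.strip():
            continue
        vals = dict(zip(cols, ln.split("\t")))
        b = blocks[int(vals["Block"]) - 1]
        row = int(vals["Row"])
        col = int(vals["Column"])
        rows.append(
            {
                "block": b.index,
                "row": row,
                "column": col,
                "id": vals["ID"],
                "name": vals.get("Name", vals["ID"]),
                "x": b.origin_x + (col - 1) * b.col_spacing,
                "y": b.origin_y + (row - 1) * b.row_spacing,
            }
        )
    return ArrayLayout(blocks=blocks, spots=pd.DataFrame(rows))
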