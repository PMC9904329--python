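"""Flat-color stimulus renderings (diagnostic quality, PNG output).

Boards, pieces and occluders are drawn with the published colors but
without shading or highlight effects; night skies come straight from the
compositing equation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .geometry import BoardSpec, OccluderSpec, PieceLayout, occluder_mask
from .sky import SkyScene

BACKGROUND_RGB = (128, 128, 128)
BOARD_RGB = (150, 150, 150)
OCCLUDER_RGB = (100, 172, 174)   # luminance 150 under 0.3R + 0.59G + 0.11B
BLACK_PIECE_RGB = (68, 68, 92)   # luminance 70
WHITE_PIECE_RGB = (226, 226, 255)  # luminance 230


def render_board(board: BoardSpec, occluder: OccluderSpec | None = None,
                 layout: PieceLayout | None = None) -> Image.Image:
    """Render board, pieces, and occluder as a flat-color RGB image."""
    w, h = board.board_px
    img = Image.new("RGB", (w, h), BOARD_RGB)
    draw = ImageDraw.Draw(img)
    if layout is not None:
        r = board.piece_px / 2.0
        for (row, col), color in zip(layout.cells, layout.colors):
            cx, cy = board.cell_center(row, col)
            rgb = BLACK_PIECE_RGB if color == "black" else WHITE_PIECE_RGB
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=rgb)
    if occluder is not None and occluder.kind != "none":
        mask = occluder_mask(board, occluder)
        arr = np.array(img)
        arr[mask] = OCCLUDER_RGB
        img = Image.fromarray(arr)
    return img


def render_sky(scene: SkyScene) -> Image.Image:
    """Render a composited night-sky scene to an 8-bit RGB image."""
    return Image.fromarray(np.round(scene.composite).astype(np.uint8), "RGB")


def save_png(img: Image.Image, path: str | Path) -> None:
    img.save(Path(path), format="PNG")
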