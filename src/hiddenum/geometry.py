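"""Boards, occluders, trial designs, and the hidden-count extrapolation.

The scene is a game board of ``rows x cols`` square-ish cells on which
pieces can be placed, partially covered by an occluder (a mesh with round
holes, or two opaque bars).  A cell counts as *hidden* when a piece centred
in it would be completely covered by occluder material; the visible/hidden
cell counts define the areas ``S_v`` and ``S_h`` that enter the
constant-density extrapolation

    n_h = n_v * S_h / S_v

(the density of visible objects, ``n_v / S_v``, applied to the hidden
area).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Base (scale = 1) stimulus dimensions, in pixels.
BASE_BOARD_PX = (390, 507)  # width x height
BASE_OCCLUDER_PX = (280, 407)
BASE_PIECE_PX = 21
DEFAULT_ROWS = 13
DEFAULT_COLS = 9

#: Mesh-occluder menu: proportion of occlusion -> (small, large) hole diameters.
MESH_MENU = {
    0.25: (25, 35),
    0.36: (30, 45),
    0.43: (35, 50),
    0.50: (39, 56),
    0.58: (40, 60),
    0.65: (54, 60),
    0.76: (58, 63),
}

STANDARD_SCALES = (1.0, 0.75, 0.5)


class GeometryError(ValueError):
    """Raised for infeasible occluder or piece-placement geometry."""


@dataclass(frozen=True)
class BoardSpec:
    """A rectangular game board divided into a grid of cells."""

    rows: int
    cols: int
    board_px: tuple[int, int]
    cell_px: int
    piece_px: int
    scale: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def cell_w(self) -> float:
        """Exact (fractional) cell width in pixels."""
        return self.board_px[0] / self.cols

    @property
    def cell_h(self) -> float:
        return self.board_px[1] / self.rows

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Pixel coordinates (x, y) of a cell centre; 0-based indices."""
        return ((col + 0.5) * self.cell_w, (row + 0.5) * self.cell_h)


@dataclass(frozen=True)
class OccluderSpec:
    """An occluding surface: a mesh with round holes, bars, or nothing.

    ``hole_centers`` holds ``(x, y, diameter)`` triples in occluder-local
    pixel coordinates.  ``bar_extent`` holds 0-based inclusive
    ``(start, stop)`` column ranges (vertical bars) or row ranges
    (horizontal bars).
    """

    kind: str  # "mesh" | "vertical_bars" | "horizontal_bars" | "none"
    occluder_px: tuple[int, int] = (0, 0)
    hole_diams: tuple[float, float] | None = None
    hole_centers: tuple[tuple[float, float, float], ...] = ()
    bar_extent: tuple[tuple[int, int], ...] = ()
    pattern_id: int = 1
    scale: float = 1.0


@dataclass(frozen=True)
class OcclusionGeometry:
    """Visible/hidden cell counts and areas for a board--occluder pair.

    ``S_v`` and ``S_h`` are in cell-count units and equal ``N_v``/``N_h``
    for geometries computed from an actual occluder; :meth:`from_ratio`
    builds a geometry from a stated area ratio instead (fractional areas,
    integer cell counts by rounding), flagged via ``ratio_source``.
    """

    N_v: int
    N_h: int
    S_v: float
    S_h: float
    ratio_source: str = "geometry"  # "geometry" | "published"
    hidden_cells: tuple[tuple[int, int], ...] = field(default=(), repr=False)

    def __post_init__(self):
        if self.N_v < 0 or self.N_h < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.N_v + self.N_h

    @property
    def ratio(self) -> float:
        """Hidden-to-visible area ratio S_h / S_v."""
        if self.S_v <= 0:
            raise ZeroDivisionError("S_v = 0: hidden/visible ratio undefined")
        return self.S_h / self.S_v

    @classmethod
    def from_ratio(cls, ratio: float, n_cells: int = 117) -> "OcclusionGeometry":
        """Geometry matching a stated hidden/visible area ratio.

        Areas are kept fractional so the ratio is honoured exactly; the
        integer cell counts (for urn models) are the rounded split.
        """
        if ratio < 0:
            raise ValueError("ratio must be non-negative")
        s_h = n_cells * ratio / (1.0 + ratio)
        s_v = n_cells - s_h
        n_h = round(s_h)
        return cls(N_v=n_cells - n_h, N_h=n_h, S_v=s_v, S_h=s_h,
                   ratio_source="published")


def make_board(rows: int = DEFAULT_ROWS, cols: int = DEFAULT_COLS,
               scale: float = 1.0) -> BoardSpec:
    """Construct a board; defaults give the 117-cell 13 x 9 board.

    Pixel dimensions are proportional to the default 390 x 507 board and
    scaled by ``scale`` (rounded to whole pixels).
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"board dimensions must be positive, got {rows}x{cols}")
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if scale not in STANDARD_SCALES:
        warnings.warn(f"non-standard scale {scale}; standard scales are "
                      f"{STANDARD_SCALES}", stacklevel=2)
    base_w = BASE_BOARD_PX[0] * cols / DEFAULT_COLS
    base_h = BASE_BOARD_PX[1] * rows / DEFAULT_ROWS
    board_px = (round(scale * base_w), round(scale * base_h))
    cell_px = round(scale * BASE_BOARD_PX[1] / DEFAULT_ROWS)
    piece_px = round(scale * BASE_PIECE_PX)
    return BoardSpec(rows=rows, cols=cols, board_px=board_px,
                     cell_px=cell_px, piece_px=max(piece_px, 1), scale=scale)


def make_mesh_occluder(small_d: float, large_d: float, pattern_id: int = 1,
                       scale: float = 1.0) -> OccluderSpec:
    """Mesh occluder with 12 round holes (6 small, 6 large).

    Holes sit on a 4 x 3 lattice inside the occluder footprint with sizes
    alternating in a checker pattern, which makes the layout
    mirror-symmetric about the vertical midline; ``pattern_id=2`` swaps
    the two size classes.  Deterministic for fixed inputs.
    """
    if not (0 < small_d < large_d):
        raise ValueError(f"need 0 < small_d < large_d, got ({small_d}, {large_d})")
    if pattern_id not in (1, 2):
        raise ValueError(f"pattern_id must be 1 or 2, got {pattern_id}")
    w = round(scale * BASE_OCCLUDER_PX[0])
    h = round(scale * BASE_OCCLUDER_PX[1])
    small = scale * small_d
    large = scale * large_d
    centers = []
    for i in range(4):          # lattice rows
        for j in range(3):      # lattice columns
            x = (j + 0.5) * w / 3.0
            y = (i + 0.5) * h / 4.0
            is_small = (i + j) % 2 == (0 if pattern_id == 1 else 1)
            d = small if is_small else large
            centers.append((x, y, d))
    # feasibility: holes inside the footprint and pairwise disjoint
    for (x, y, d) in centers:
        r = d / 2.0
        if x - r < 0 or x + r > w or y - r < 0 or y + r > h:
            raise GeometryError(f"hole at ({x:.1f},{y:.1f}) d={d} exceeds "
                                f"occluder bounds {w}x{h}")
    for a in range(len(centers)):
        for b in range(a + 1, len(centers)):
            xa, ya, da = centers[a]
            xb, yb, db = centers[b]
            if math.hypot(xa - xb, ya - yb) < (da + db) / 2.0:
                raise GeometryError("mesh holes overlap")
    return OccluderSpec(kind="mesh", occluder_px=(w, h),
                        hole_diams=(small, large),
                        hole_centers=tuple(centers),
                        pattern_id=pattern_id, scale=scale)


# 0-based inclusive ranges; two vertical bars of two columns each and two
# horizontal bars of three rows each, symmetric and clear of the board edges.
VERTICAL_BAR_COLS = ((2, 3), (5, 6))
HORIZONTAL_BAR_ROWS = ((3, 5), (7, 9))


def make_bar_occluder(orientation: str) -> OccluderSpec:
    """Bar occluder: two vertical bars (2 columns each) or two horizontal
    bars (3 rows each), spanning the full board."""
    if orientation == "vertical":
        return OccluderSpec(kind="vertical_bars", bar_extent=VERTICAL_BAR_COLS)
    if orientation == "horizontal":
        return OccluderSpec(kind="horizontal_bars", bar_extent=HORIZONTAL_BAR_ROWS)
    raise ValueError(f"orientation must be 'vertical' or 'horizontal', "
                     f"got {orientation!r}")


def no_occluder() -> OccluderSpec:
    """An occluder with zero footprint (fully visible board)."""
    return OccluderSpec(kind="none")


def occluder_mask(board: BoardSpec, occluder: OccluderSpec) -> np.ndarray:
    """Boolean (H x W) mask of occluder material on the board pixel grid.

    The occluder is centred on the board.  Pixel (iy, ix) samples the
    material at its centre (ix + 0.5, iy + 0.5).
    """
    w, h = board.board_px
    mask = np.zeros((h, w), dtype=bool)
    if occluder.kind == "none":
        return mask
    if occluder.kind == "mesh":
        ow, oh = occluder.occluder_px
        x0 = (w - ow) / 2.0
        y0 = (h - oh) / 2.0
        xs = np.arange(w) + 0.5
        ys = np.arange(h) + 0.5
        inside = ((xs >= x0) & (xs <= x0 + ow))[None, :] & \
                 ((ys >= y0) & (ys <= y0 + oh))[:, None]
        mask[:] = inside
        xg, yg = np.meshgrid(xs, ys)
        for (hx, hy, d) in occluder.hole_centers:
            r2 = (d / 2.0) ** 2
            mask &= (xg - (x0 + hx)) ** 2 + (yg - (y0 + hy)) ** 2 > r2
        return mask
    if occluder.kind == "vertical_bars":
        xs = np.arange(w) + 0.5
        for (c0, c1) in occluder.bar_extent:
            lo = c0 * board.cell_w
            hi = (c1 + 1) * board.cell_w
            mask[:, (xs >= lo) & (xs <= hi)] = True
        return mask
    if occluder.kind == "horizontal_bars":
        ys = np.arange(h) + 0.5
        for (r0, r1) in occluder.bar_extent:
            lo = r0 * board.cell_h
            hi = (r1 + 1) * board.cell_h
            mask[(ys >= lo) & (ys <= hi), :] = True
        return mask
    raise ValueError(f"unknown occluder kind {occluder.kind!r}")


def occlusion_geometry(board: BoardSpec,
                       occluder: OccluderSpec) -> OcclusionGeometry:
    """Count cells where a centred piece would be completely hidden.

    A cell is hidden iff every pixel of a piece disk (diameter
    ``board.piece_px``) centred in the cell lies under occluder material;
    evaluated on a rasterised mask at native pixel resolution.
    """
    mask = occluder_mask(board, occluder)
    h, w = mask.shape
    r = board.piece_px / 2.0
    hidden: list[tuple[int, int]] = []
    for row in range(board.rows):
        for col in range(board.cols):
            cx, cy = board.cell_center(row, col)
            ix0 = max(int(math.floor(cx - r)), 0)
            ix1 = min(int(math.ceil(cx + r)), w)
            iy0 = max(int(math.floor(cy - r)), 0)
            iy1 = min(int(math.ceil(cy + r)), h)
            xs = np.arange(ix0, ix1) + 0.5
            ys = np.arange(iy0, iy1) + 0.5
            in_disk = ((xs - cx) ** 2)[None, :] + ((ys - cy) ** 2)[:, None] <= r * r
            if np.all(mask[iy0:iy1, ix0:ix1][in_disk]):
                hidden.append((row, col))
    n_h = len(hidden)
    n_v = board.n_cells - n_h
    return OcclusionGeometry(N_v=n_v, N_h=n_h, S_v=float(n_v), S_h=float(n_h),
                             hidden_cells=tuple(hidden))


def expected_hidden(n_v: float, geom: OcclusionGeometry) -> float:
    """Constant-density expected hidden count: ``n_v * S_h / S_v``.

    The density of visible objects, ``n_v / S_v``, is extrapolated to the
    hidden area ``S_h``.
    """
    if n_v < 0:
        raise ValueError("n_v must be non-negative")
    if geom.S_v <= 0:
        raise ZeroDivisionError("S_v = 0: visible density undefined, cannot "
                                "extrapolate a hidden count")
    return n_v * geom.S_h / geom.S_v


# ---------------------------------------------------------------------------
# Trial designs

TRIAL_COLUMNS = ["experiment", "trial", "condition", "n_visible_std",
                 "n_visible_cmp", "occluder", "scale", "rep", "analyzed"]

#: Per-experiment design menus.
DESIGN_DEFAULTS: dict[int, dict] = {
    1: {
        "standard": 10,
        "comparisons": [2, 4, 6, 8, 9, 10, 11, 12, 14, 16, 18],
        "conditions": ["non_occluded", "occluded", "mixed"],
        "repetitions": 10,
        "occluder": "mesh_40_60",
    },
    2: {
        "numerosities": list(range(6, 15)),
        "conditions": ["non_occluded", "small_occluder", "large_occluder"],
        "repetitions": 10,
        "occluders": {"non_occluded": "none", "small_occluder": "mesh_40_60",
                      "large_occluder": "mesh_30_45"},
    },
    3: {
        "proportions": [0.25, 0.36, 0.43, 0.50, 0.58, 0.65, 0.76],
        "scales": [1.0, 0.75, 0.5],
        "repetitions": 10,
    },
    4: {
        "numerosities": [5, 7, 10, 12, 14],
        "conditions": ["irregular", "regular_across", "regular_outside"],
        "repetitions": 10,
        # vertical bars for 5/10/12, horizontal bars for 7/14
        "occluder_by_n": {5: "vertical_bars", 10: "vertical_bars",
                          12: "vertical_bars", 7: "horizontal_bars",
                          14: "horizontal_bars"},
    },
    5: {
        "numerosities": list(range(6, 15)),
        "proportions": [round(0.30 + 0.02 * k, 2) for k in range(21)],
    },
}


def enumerate_trials(experiment_id: int, config: dict | None = None) -> pd.DataFrame:
    """Enumerate the trial table for one of the five experiments.

    Returns a DataFrame with columns
    ``(experiment, trial, condition, n_visible_std, n_visible_cmp,
    occluder, scale, rep, analyzed)``.  Obscured and swapped trials carry
    ``analyzed=False``.  Default menus reproduce the published designs
    (352 / 279 / 231 / 150 / 189 trials); ``config`` overrides menu
    entries by key.
    """
    if experiment_id not in DESIGN_DEFAULTS:
        raise ValueError(f"unknown experiment_id {experiment_id!r}; expected 1-5")
    menu = dict(DESIGN_DEFAULTS[experiment_id])
    if config:
        menu.update(config)
    rows: list[dict] = []

    def add(condition, n_std, n_cmp, occ, scale, rep, analyzed=True):
        rows.append(dict(experiment=experiment_id, trial=len(rows),
                         condition=condition, n_visible_std=n_std,
                         n_visible_cmp=n_cmp, occluder=occ, scale=scale,
                         rep=rep, analyzed=analyzed))

    if experiment_id == 1:
        std = menu["standard"]
        for cond in menu["conditions"]:
            occ = "none" if cond == "non_occluded" else menu["occluder"]
            for n_cmp in menu["comparisons"]:
                for rep in range(menu["repetitions"]):
                    add(cond, std, n_cmp, occ, 1.0, rep)
        for n_cmp in menu["comparisons"]:   # obscured demonstrations
            add("obscured", std, n_cmp, menu["occluder"], 1.0, 0, analyzed=False)
        for n_cmp in menu["comparisons"]:   # swapped: comparison occluded
            add("swapped", std, n_cmp, menu["occluder"], 1.0, 0, analyzed=False)

    elif experiment_id == 2:
        for cond in menu["conditions"]:
            occ = menu["occluders"][cond]
            for n in menu["numerosities"]:
                for rep in range(menu["repetitions"]):
                    add(cond, n, None, occ, 1.0, rep)
        for n in menu["numerosities"]:
            add("obscured", n, None, menu["occluders"]["small_occluder"],
                1.0, 0, analyzed=False)

    elif experiment_id == 3:
        for p in menu["proportions"]:
            occ = "mesh_{}_{}".format(*MESH_MENU[p]) if p in MESH_MENU else f"mesh_p{p}"
            for s in menu["scales"]:
                for rep in range(menu["repetitions"]):
                    add("occluded", p, None, occ, s, rep)
        for p in menu["proportions"]:
            for s in menu["scales"]:
                add("non_occluded", p, None, "none", s, 0)

    elif experiment_id == 4:
        for cond in menu["conditions"]:
            for n in menu["numerosities"]:
                occ = menu["occluder_by_n"][n]
                for rep in range(menu["repetitions"]):
                    add(cond, n, None, occ, 1.0, rep)

    elif experiment_id == 5:
        for n in menu["numerosities"]:
            for p in menu["proportions"]:
                add("sky", n, p, "clouds", 1.0, 0)

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# Piece placement

@dataclass(frozen=True)
class PieceLayout:
    """Placed pieces: 0-based (row, col) cells with black/white colors."""

    cells: tuple[tuple[int, int], ...]
    colors: tuple[str, ...]
    arrangement: str
    n_visible: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"row": [c[0] for c in self.cells],
                             "col": [c[1] for c in self.cells],
                             "color": list(self.colors)})


def _balanced_colors(n: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Black/white colors differing in count by at most one, shuffled."""
    colors = ["black"] * (n // 2) + ["white"] * (n - n // 2)
    rng.shuffle(colors)
    return tuple(colors)


def _has_collinear_triplet(cells: list[tuple[int, int]]) -> bool:
    """True if three pieces occupy contiguous collinear cells (a visually
    salient line segment in any of the four grid directions).

    A stricter "no three anywhere on a shared row/column" rule is
    unsatisfiable at the published numerosities (12 pieces on the 5
    visible columns of the vertical-bar board force three into one
    column), so line-ness is judged on contiguous runs.
    """
    occupied = set(cells)
    for (r, c) in occupied:
        for (dr, dc) in ((0, 1), (1, 0), (1, 1), (1, -1)):
            if (r + dr, c + dc) in occupied and (r + 2 * dr, c + 2 * dc) in occupied:
                return True
    return False


def place_pieces(board: BoardSpec, occluder: OccluderSpec, n_visible: int,
                 arrangement: str = "irregular",
                 rng_seed: int | None = None) -> PieceLayout:
    """Place ``n_visible`` pieces on visible cells of the board.

    ``irregular`` scatters pieces with no three on contiguous collinear
    cells (so the scatter never contains a salient line segment).
    ``regular_across`` arranges pieces in lines
    perpendicular to the bars so each used line crosses the occluded
    region; ``regular_outside`` arranges them in fully visible lines
    parallel to the bars.  When a single line cannot hold ``n_visible``
    visible pieces, consecutive parallel lines are filled (the published
    numerosities fill whole lines for all but one case).
    """
    if n_visible < 0:
        raise ValueError("n_visible must be non-negative")
    geom = occlusion_geometry(board, occluder)
    hidden = set(geom.hidden_cells)
    visible_cells = [(r, c) for r in range(board.rows) for c in range(board.cols)
                     if (r, c) not in hidden]
    if n_visible > len(visible_cells):
        raise GeometryError(f"cannot place {n_visible} pieces on "
                            f"{len(visible_cells)} visible cells")
    rng = np.random.default_rng(rng_seed)

    if n_visible == 0:
        return PieceLayout(cells=(), colors=(), arrangement=arrangement,
                           n_visible=0, seed=rng_seed)

    if arrangement == "irregular":
        cells = _place_irregular(visible_cells, n_visible, rng)
    elif arrangement in ("regular_across", "regular_outside"):
        cells = _place_regular(board, occluder, hidden, n_visible,
                               arrangement, rng)
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    return PieceLayout(cells=tuple(cells), colors=_balanced_colors(n_visible, rng),
                       arrangement=arrangement, n_visible=n_visible,
                       seed=rng_seed)


def _place_irregular(visible_cells, n, rng, max_tries: int = 5000):
    # For very small boards the no-line constraint can be unsatisfiable in
    # which case we fall back to an unconstrained sample after max_tries.
    idx = np.arange(len(visible_cells))
    best = None
    for _ in range(max_tries):
        pick = rng.choice(idx, size=n, replace=False)
        cells = [visible_cells[i] for i in pick]
        if n < 3 or not _has_collinear_triplet(cells):
            return cells
        best = cells
    warnings.warn("irregular placement: no-three-on-a-line constraint not "
                  "satisfied after retries; returning last sample", stacklevel=2)
    return best


def _place_regular(board, occluder, hidden, n, arrangement, rng):
    if occluder.kind == "vertical_bars":
        across_lines = [[(r, c) for c in range(board.cols)]
                        for r in range(board.rows)]          # rows cross bars
        covered = {c for (c0, c1) in occluder.bar_extent
                   for c in range(c0, c1 + 1)}
        outside_lines = [[(r, c) for r in range(board.rows)]
                         for c in range(board.cols) if c not in covered]
    elif occluder.kind == "horizontal_bars":
        across_lines = [[(r, c) for r in range(board.rows)]
                        for c in range(board.cols)]          # columns cross bars
        covered = {r for (r0, r1) in occluder.bar_extent
                   for r in range(r0, r1 + 1)}
        outside_lines = [[(r, c) for c in range(board.cols)]
                         for r in range(board.rows) if r not in covered]
    else:
        raise GeometryError("regular arrangements require a bar occluder")

    lines = across_lines if arrangement == "regular_across" else outside_lines
    # keep only visible cells on each line; across-lines must intersect the
    # occluded region, outside-lines must not (guaranteed by construction)
    usable = []
    for line in lines:
        vis = [rc for rc in line if rc not in hidden]
        crosses = len(vis) < len(line)
        if arrangement == "regular_across" and not crosses:
            continue
        if vis:
            usable.append(vis)
    if sum(len(v) for v in usable) < n:
        raise GeometryError(f"no set of qualifying lines holds {n} visible "
                            f"pieces for arrangement {arrangement}")
    # fill whole lines starting near the board centre, remainder contiguous
    order = np.argsort([abs(i - len(usable) / 2 + 0.5) for i in range(len(usable))])
    cells: list[tuple[int, int]] = []
    for i in order:
        take = min(n - len(cells), len(usable[i]))
        cells.extend(usable[i][:take])
        if len(cells) == n:
            break
    return cells
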