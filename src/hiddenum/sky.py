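"""Procedural night-sky stimuli: clouds from Brownian noise, stars, and a
weighted composite.

A scene is a 500 x 500 RGB image built from three layers: a blue gradient
sky, a flat white cloud layer, and a star layer.  The cloud weight field
comes from a Brownian (1/f^2) noise map shifted down and clamped at zero;
the star weight field from Gaussian-smoothed star stamps.  The composite is

    I = (1 - w_cloud) * [(1 - w_star) * I_sky + w_star * I_star]
        + w_cloud * I_cloud

per pixel and channel.  The ground-truth cloud cover is the fraction of
pixels whose cloud weight exceeds a small visibility threshold, and can be
calibrated to a target proportion by adjusting the subtraction offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

SKY_SIZE = 500
#: gradient endpoints, upper-left (light blue) to lower-right (dark blue)
SKY_LIGHT = (49, 87, 133)
SKY_DARK = (10, 25, 44)
CLOUD_RGB = (255, 255, 255)
#: star classes: (edge px, RGB, smoothing variance)
STAR_SMALL = (2, (220, 220, 160), 0.9)
STAR_LARGE = (3, (176, 176, 128), 1.2)
DEFAULT_OFFSET = 0.6
DEFAULT_TAU = 0.05


class CalibrationError(ValueError):
    """Raised when a target cloud cover cannot be reached."""


class PlacementError(ValueError):
    """Raised when stars cannot be placed on uncovered sky."""


@dataclass
class SkyScene:
    """All layers and ground truth for one night-sky stimulus."""

    I_sky: np.ndarray
    I_cloud: np.ndarray
    I_star: np.ndarray
    w_cloud: np.ndarray
    w_star: np.ndarray
    star_positions: list[tuple[int, int, str]]  # (row, col, "small"|"large")
    cover_proportion: float
    offset: float
    composite: np.ndarray
    seed: int | None = None

    @property
    def n_visible(self) -> int:
        return len(self.star_positions)

    def sidecar_frame(self):
        """Per-scene metadata table: star positions/classes plus the
        scene-level cover proportion, offset, and seed."""
        import pandas as pd
        return pd.DataFrame({
            "row": [r for (r, _, _) in self.star_positions],
            "col": [c for (_, c, _) in self.star_positions],
            "size_class": [k for (_, _, k) in self.star_positions],
            "cover_proportion": self.cover_proportion,
            "offset": self.offset,
            "seed": self.seed,
        })


def brownian_noise(size: int, rng_seed: int | None = None) -> np.ndarray:
    """Brownian (1/f^2 power) noise field, min-max normalized to [0, 1].

    Synthesized by spectral shaping: complex white noise is weighted by
    1/f in amplitude (1/f^2 in power) with the DC term zeroed, and the
    inverse FFT's real part is rescaled to [0, 1].
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    rng = np.random.default_rng(rng_seed)
    white = rng.normal(size=(size, size)) + 1j * rng.normal(size=(size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = 1.0 / f[nonzero]
    field = np.fft.ifft2(white * amp).real
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo)


def make_cloud_weight(noise: np.ndarray, offset: float = DEFAULT_OFFSET) -> np.ndarray:
    """Cloud weight field: shift the noise down by ``offset`` and clamp
    negatives at zero."""
    return np.clip(noise - offset, 0.0, None)


def cover_fraction(w_cloud: np.ndarray, tau: float = DEFAULT_TAU) -> float:
    """Fraction of pixels considered cloud-covered (weight above tau)."""
    return float(np.mean(w_cloud > tau))


def calibrate_cover(noise: np.ndarray, target: float,
                    tau: float = DEFAULT_TAU,
                    tol: float = 0.005) -> tuple[float, float]:
    """Find the subtraction offset giving a target cloud-cover proportion.

    The covered fraction ``P(noise - offset > tau)`` is non-increasing in
    the offset, so the (1 - target) quantile of the noise gives the answer
    directly; a small bisection refines it against the discrete pixel
    grid.  Returns ``(offset, achieved)``.
    """
    if not 0 < target < 1:
        raise ValueError("target proportion must be in (0, 1)")
    flat = np.sort(noise, axis=None)
    # offset such that a fraction `target` of pixels exceeds offset + tau
    q = float(np.quantile(flat, 1.0 - target))
    offset = max(q - tau, 0.0)
    achieved = cover_fraction(make_cloud_weight(noise, offset), tau)
    if abs(achieved - target) > tol:
        # refine by bisection on the sorted values
        lo, hi = 0.0, float(flat[-1])
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            a = cover_fraction(make_cloud_weight(noise, mid), tau)
            if a > target:
                lo = mid
            else:
                hi = mid
            if abs(a - target) <= tol:
                offset, achieved = mid, a
                break
        else:
            offset = 0.5 * (lo + hi)
            achieved = cover_fraction(make_cloud_weight(noise, offset), tau)
    if abs(achieved - target) > tol:
        raise CalibrationError(f"cannot reach cover {target} (best {achieved})")
    return offset, achieved


def sky_gradient(size: int = SKY_SIZE) -> np.ndarray:
    """Background sky: light blue to dark blue from upper-left to
    lower-right."""
    ramp = (np.arange(size)[:, None] + np.arange(size)[None, :]) / (2.0 * (size - 1))
    light = np.array(SKY_LIGHT, dtype=float)
    dark = np.array(SKY_DARK, dtype=float)
    return light[None, None, :] + ramp[:, :, None] * (dark - light)[None, None, :]


def make_star_layer(n_visible: int, w_cloud: np.ndarray,
                    rng_seed: int | None = None,
                    tau: float = DEFAULT_TAU
                    ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, str]]]:
    """Place stars on uncovered sky and build the star image and weight.

    Half the stars are small (2 x 2, luminance 213), half large (3 x 3,
    luminance 171); for odd counts the split differs by one.  Each star's
    whole footprint must sit on pixels with ``w_cloud <= tau``.  The star
    weight field is the union of footprints smoothed with the class
    variance (0.9 small, 1.2 large), clipped to [0, 1].
    """
    if n_visible < 0:
        raise ValueError("n_visible must be non-negative")
    size = w_cloud.shape[0]
    rng = np.random.default_rng(rng_seed)
    I_star = np.zeros((size, size, 3), dtype=float)
    w_star = np.zeros((size, size), dtype=float)
    positions: list[tuple[int, int, str]] = []
    if n_visible == 0:
        return I_star, w_star, positions

    n_small = n_visible // 2 + (rng.integers(2) if n_visible % 2 else 0)
    classes = ["small"] * int(n_small) + ["large"] * (n_visible - int(n_small))
    rng.shuffle(classes)

    clear = w_cloud <= tau
    occupied = np.zeros_like(clear)
    stamp_masks = {name: (edge, np.array(rgb, dtype=float), var)
                   for name, (edge, rgb, var)
                   in (("small", STAR_SMALL), ("large", STAR_LARGE))}

    for name in classes:
        edge, rgb, var = stamp_masks[name]
        placed = False
        for _ in range(10_000):
            r = int(rng.integers(0, size - edge + 1))
            c = int(rng.integers(0, size - edge + 1))
            foot = (slice(r, r + edge), slice(c, c + edge))
            if clear[foot].all() and not occupied[foot].any():
                stamp_field = np.zeros((size, size), dtype=float)
                stamp_field[foot] = 1.0
                w_star = np.clip(
                    w_star + ndimage.gaussian_filter(stamp_field, np.sqrt(var)),
                    0.0, 1.0)
                I_star[foot] = rgb
                occupied[foot] = True
                positions.append((r, c, name))
                placed = True
                break
        if not placed:
            raise PlacementError(f"no uncovered room left for a {name} star "
                                 f"({len(positions)} of {n_visible} placed)")
    return I_star, np.clip(w_star, 0.0, 1.0), positions


def compose_sky(I_sky: np.ndarray, I_star: np.ndarray, I_cloud: np.ndarray,
                w_cloud: np.ndarray, w_star: np.ndarray) -> np.ndarray:
    """Weighted composite of sky, star, and cloud layers (see module
    docstring), clipped to [0, 255]."""
    shapes = {I_sky.shape[:2], I_star.shape[:2], I_cloud.shape[:2],
              w_cloud.shape, w_star.shape}
    if len(shapes) != 1:
        raise ValueError(f"layer shapes differ: {shapes}")
    if (w_cloud < 0).any() or (w_cloud > 1).any() or \
       (w_star < 0).any() or (w_star > 1).any():
        raise ValueError("weights must lie in [0, 1]")
    wc = w_cloud[..., None]
    ws = w_star[..., None]
    out = (1 - wc) * ((1 - ws) * I_sky + ws * I_star) + wc * I_cloud
    return np.clip(out, 0.0, 255.0)


def make_sky_scene(n_visible: int, cover: float,
                   rng_seed: int | None = None,
                   size: int = SKY_SIZE,
                   tau: float = DEFAULT_TAU) -> SkyScene:
    """Build a complete scene with a calibrated cloud cover proportion."""
    noise = brownian_noise(size, rng_seed)
    offset, achieved = calibrate_cover(noise, cover, tau)
    w_cloud = make_cloud_weight(noise, offset)
    star_seed = None if rng_seed is None else rng_seed + 1
    I_star, w_star, positions = make_star_layer(n_visible, w_cloud,
                                                star_seed, tau)
    I_sky = sky_gradient(size)
    I_cloud = np.full((size, size, 3), 255.0)
    composite = compose_sky(I_sky, I_star, I_cloud, w_cloud, w_star)
    return SkyScene(I_sky=I_sky, I_cloud=I_cloud, I_star=I_star,
                    w_cloud=w_cloud, w_star=w_star,
                    star_positions=positions, cover_proportion=achieved,
                    offset=offset, composite=composite, seed=rng_seed)
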