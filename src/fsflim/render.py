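"""Spectral false-color rendering, lifetime-image rendering, and tile stitching.

Color images are built by assigning each spectral channel an RGB triple
according to its center wavelength and summing the per-channel contributions
into one RGB value per pixel, normalized to the brightest component in the
image (or across a whole mosaic).  Per-pixel opacity follows total intensity
("intensity-weighted transparency"), optionally inverted to bring out the
low-count regions.

Lifetime maps are rendered through a perceptually ordered colormap over a
stated lifetime range, again with intensity-weighted (or inverted) alpha;
pixels without a valid fit are fully transparent.

Mosaics are assembled on a pure translation grid from the stage step and
pixel pitch, with plain averaging in the overlap strips and global
normalization to the brightest pixel across all tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import SpectralAxis

__all__ = [
    "ColorImage",
    "TileLayout",
    "wavelength_to_rgb",
    "render_color_image",
    "render_lifetime_image",
    "stitch_tiles",
]

# Rendering gamut of the piecewise-linear visible-spectrum map (nm).
GAMUT_MIN = 380.0
GAMUT_MAX = 780.0


@dataclass
class ColorImage:
    """RGB + alpha raster, all components in [0, 1].

    ``normalization`` records the intensity scalar the image was divided by,
    so tiles of a mosaic can share one global scale.
    """

    rgb: np.ndarray  # (rows, cols, 3)
    alpha: np.ndarray  # (rows, cols)
    normalization: float

    def __post_init__(self) -> None:
        if np.any(self.rgb < -1e-9) or np.any(self.rgb > 1 + 1e-9):
            raise ValueError("rgb components must lie in [0, 1]")
        if np.any(self.alpha < -1e-9) or np.any(self.alpha > 1 + 1e-9):
            raise ValueError("alpha must lie in [0, 1]")

    def to_rgba(self) -> np.ndarray:
        """(rows, cols, 4) float array, alpha in the last plane."""
        return np.dstack([self.rgb, self.alpha])


@dataclass(frozen=True)
class TileLayout:
    """Translation grid of stage-scanned tiles.

    The overlap is derived from ``field_of_view - step`` rather than stored,
    so the geometry is always self-consistent.
    """

    grid_rows: int
    grid_cols: int
    step: float  # µm between tile origins
    field_of_view: float  # µm per tile side
    pixel_pitch: float  # µm per pixel

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid extents must be >= 1")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.step > self.field_of_view:
            raise ValueError(
                f"step {self.step} µm exceeds field of view {self.field_of_view} µm "
                "(tiles must overlap or abut)"
            )

    @property
    def overlap(self) -> float:
        """Overlap between adjacent tiles in µm (>= 0)."""
        return self.field_of_view - self.step

    @property
    def step_px(self) -> int:
        """Tile origin spacing in pixels."""
        return round(self.step / self.pixel_pitch)


def wavelength_to_rgb(wavelength: float | np.ndarray) -> np.ndarray:
    """Piecewise-linear visible-spectrum RGB approximation.

    Maps 380-780 nm onto [0,1]^3 with linear hue segments (violet → blue →
    cyan → green → yellow → red) and linear intensity tapers below 420 nm and
    above 700 nm.  Deterministic and continuous; outside the gamut the result
    is black.  Vectorized over the input.
    """
    lam = np.asarray(wavelength, dtype=float)
    r = np.zeros_like(lam)
    g = np.zeros_like(lam)
    b = np.zeros_like(lam)

    seg = (lam >= 380) & (lam < 440)
    r[seg] = (440 - lam[seg]) / 60.0
    b[seg] = 1.0
    seg = (lam >= 440) & (lam < 490)
    g[seg] = (lam[seg] - 440) / 50.0
    b[seg] = 1.0
    seg = (lam >= 490) & (lam < 510)
    g[seg] = 1.0
    b[seg] = (510 - lam[seg]) / 20.0
    seg = (lam >= 510) & (lam < 580)
    r[seg] = (lam[seg] - 510) / 70.0
    g[seg] = 1.0
    seg = (lam >= 580) & (lam < 645)
    r[seg] = 1.0
    g[seg] = (645 - lam[seg]) / 65.0
    seg = (lam >= 645) & (lam <= GAMUT_MAX)
    r[seg] = 1.0

    taper = np.ones_like(lam)
    lo = (lam >= 380) & (lam < 420)
    taper[lo] = 0.3 + 0.7 * (lam[lo] - 380) / 40.0
    hi = (lam > 700) & (lam <= GAMUT_MAX)
    taper[hi] = 0.3 + 0.7 * (GAMUT_MAX - lam[hi]) / 80.0
    out = (lam >= GAMUT_MIN) & (lam <= GAMUT_MAX)
    taper[~out] = 0.0

    rgb = np.stack([r * taper, g * taper, b * taper], axis=-1)
    return rgb


def render_color_image(
    intensity: np.ndarray,
    axis: SpectralAxis,
    *,
    max_component: float | None = None,
    max_total: float | None = None,
) -> ColorImage:
    """Sum per-channel spectral contributions into an RGB image.

    Per pixel, ``RGB = sum_k intensity(k) * wavelength_to_rgb(center_k)``,
    divided by the brightest RGB component in the image; alpha is total
    intensity over the brightest total intensity.  Pass ``max_component`` /
    ``max_total`` to normalize a tile against a whole mosaic instead.  An
    all-zero image renders as all-zero RGB with alpha 0.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape[-1] != axis.n_channels:
        raise ValueError(
            f"intensity has {intensity.shape[-1]} channels, axis has {axis.n_channels}"
        )
    channel_rgb = wavelength_to_rgb(axis.centers)  # (K, 3)
    rgb = intensity @ channel_rgb  # (rows, cols, 3)
    total = intensity.sum(axis=-1)

    norm = float(rgb.max()) if max_component is None else float(max_component)
    tmax = float(total.max()) if max_total is None else float(max_total)
    if norm > 0:
        rgb = np.clip(rgb / norm, 0.0, 1.0)
    alpha = np.clip(total / tmax, 0.0, 1.0) if tmax > 0 else np.zeros_like(total)
    return ColorImage(rgb=rgb, alpha=alpha, normalization=norm)


def render_lifetime_image(
    tau_map: np.ndarray,
    intensity: np.ndarray,
    tau_range: tuple[float, float],
    *,
    invert_alpha: bool = False,
    cmap: str = "viridis",
    max_intensity: float | None = None,
) -> ColorImage:
    """Render a single-channel lifetime map with intensity-weighted alpha.

    ``tau_map`` is colored through a perceptually ordered colormap clipped to
    ``tau_range`` (ns); alpha is the normalized intensity, or its complement
    when ``invert_alpha`` — inversion brings out the low-count regions.
    Invalid pixels (``tau = 0``) are fully transparent either way.
    """
    import matplotlib

    tau_lo, tau_hi = tau_range
    if not tau_lo < tau_hi:
        raise ValueError(f"invalid tau_range {tau_range}")
    tau_map = np.asarray(tau_map, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if tau_map.shape != intensity.shape:
        raise ValueError("tau_map and intensity shapes differ")

    frac = np.clip((tau_map - tau_lo) / (tau_hi - tau_lo), 0.0, 1.0)
    rgb = matplotlib.colormaps[cmap](frac)[..., :3]

    imax = float(intensity.max()) if max_intensity is None else float(max_intensity)
    alpha = np.clip(intensity / imax, 0.0, 1.0) if imax > 0 else np.zeros_like(intensity)
    if invert_alpha:
        alpha = 1.0 - alpha
    invalid = tau_map <= 0
    alpha = np.where(invalid, 0.0, alpha)
    rgb[invalid] = 0.0
    return ColorImage(rgb=rgb, alpha=alpha, normalization=imax)


def stitch_tiles(
    tiles: list[np.ndarray], layout: TileLayout, *, normalize: bool = False
) -> np.ndarray:
    """Place tiles on the translation grid, averaging in the overlap strips.

    Tiles are ordered row-major over the grid; all must share one pixel
    extent.  Outside overlap regions the mosaic reproduces the tile values
    exactly.  With ``normalize`` the mosaic is divided by its brightest pixel
    — the sample-wide intensity normalization used before rendering.
    """
    if len(tiles) != layout.grid_rows * layout.grid_cols:
        raise ValueError(
            f"{len(tiles)} tiles for a {layout.grid_rows}x{layout.grid_cols} grid"
        )
    tiles = [np.asarray(t, dtype=float) for t in tiles]
    shape0 = tiles[0].shape
    if any(t.shape != shape0 for t in tiles):
        raise ValueError("all tiles must share one pixel extent")
    h, w = shape0[:2]
    extra = shape0[2:]
    step = layout.step_px
    rows_px = (layout.grid_rows - 1) * step + h
    cols_px = (layout.grid_cols - 1) * step + w

    acc = np.zeros((rows_px, cols_px, *extra))
    cover = np.zeros((rows_px, cols_px))
    for i, tile in enumerate(tiles):
        gy, gx = divmod(i, layout.grid_cols)
        y0, x0 = gy * step, gx * step
        acc[y0 : y0 + h, x0 : x0 + w] += tile
        cover[y0 : y0 + h, x0 : x0 + w] += 1.0
    cov = cover if not extra else cover[..., None]
    mosaic = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    if normalize:
        peak = mosaic.max()
        if peak > 0:
            mosaic = mosaic / peak
    return mosaic
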