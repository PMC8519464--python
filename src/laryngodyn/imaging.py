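"""Glottic-plane image container, phantom rendering and area segmentation.

The glottic area (GA) is measured on an axial CT slice at the level of the
vocal folds as the area of air attenuation enclosed by the folds. This module
provides the in-memory slice container (:class:`GlottisImage`), a threshold +
largest-connected-component segmentation (:func:`segment_glottic_area`), and a
synthetic phantom renderer (:func:`render_glottis_slice`) that draws a glottal
aperture of a requested area so the segmentation can be validated round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

AIR_HU = -1000.0
SOFT_TISSUE_HU = 40.0
#: Default air/tissue cut: halfway-ish between air and soft tissue.
DEFAULT_AIR_THRESHOLD_HU = -400.0

# 4-connectivity: areas touching only diagonally are separate apertures.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass(frozen=True)
class GlottisImage:
    """A 2-D axial attenuation slice with isotropic pixel spacing.

    ``roi`` is a half-open pixel rectangle ``(row0, row1, col0, col1)``
    delimiting the region in which the glottis is sought.
    """

    pixels: np.ndarray
    pixel_spacing: float
    roi: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        object.__setattr__(self, "pixels", px)
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        r0, r1, c0, c1 = self.roi
        nr, nc = px.shape
        if not (0 <= r0 <= r1 <= nr and 0 <= c0 <= c1 <= nc):
            raise ValueError(f"roi {self.roi} outside image bounds {px.shape}")

    @property
    def pixel_area(self) -> float:
        """Area of one pixel, mm^2."""
        return self.pixel_spacing**2


def segment_glottic_area(
    image: GlottisImage, hu_threshold: float = DEFAULT_AIR_THRESHOLD_HU
) -> float:
    """Segment the glottic air area within the ROI, in mm^2.

    Pixels strictly below ``hu_threshold`` are classified as air; the largest
    4-connected air component is taken as the glottis and its pixel count is
    converted to mm^2. Returns 0 when no pixel in the ROI is below threshold.
    """
    r0, r1, c0, c1 = image.roi
    sub = image.pixels[r0:r1, c0:c1]
    if sub.size == 0:
        raise ValueError("empty ROI")
    air = sub < hu_threshold
    if not air.any():
        return 0.0
    labels, n_comp = ndimage.label(air, structure=_CROSS)
    counts = np.bincount(labels.ravel())[1:]
    return float(counts.max() * image.pixel_area)


def _aperture_half_width(u: np.ndarray, iad: float, bowing: float) -> np.ndarray:
    """Half-width (mm) of the glottal aperture at relative position u.

    u runs from 0 at the anterior commissure to 1 at the posterior
    (inter-arytenoid) edge, where the full width equals the IAD. A positive
    ``bowing`` coefficient bulges the mid-membranous margin outward without
    changing the posterior width, mimicking vocal-fold bowing.
    """
    return (iad / 2.0) * u + bowing * iad * np.sin(np.pi * u)


def render_glottis_slice(
    iad: float,
    ga_target: float,
    bowing: float = 0.0,
    pixel_spacing: float = 0.5,
    shape: tuple[int, int] = (64, 64),
) -> GlottisImage:
    """Render a synthetic axial slice whose air aperture has area ``ga_target``.

    The aperture is a fore-shortened triangle (anterior commissure to a
    posterior edge of width ``iad``) with an optional bowing bulge. Its
    antero-posterior length is chosen so that the *rasterized* air area is as
    close as possible to ``ga_target`` (within 2 pixel-areas for targets that
    fit in the image).

    Raises ``ValueError`` when the requested area or width cannot fit inside
    the image bounds.
    """
    if iad <= 0:
        raise ValueError("iad must be positive")
    if ga_target < 0:
        raise ValueError("ga_target must be non-negative")
    if bowing < 0:
        raise ValueError("bowing must be non-negative")

    nrows, ncols = shape
    h = pixel_spacing
    # pixel-centre coordinates, mm, origin at image centre; y increases with row
    ys = (np.arange(nrows) - (nrows - 1) / 2.0) * h
    xs = (np.arange(ncols) - (ncols - 1) / 2.0) * h
    Y, X = np.meshgrid(ys, xs, indexing="ij")

    max_half_width = iad / 2.0 + bowing * iad
    if 2 * max_half_width > (ncols - 4) * h:
        raise ValueError("aperture wider than the image")

    # posterior edge fixed at 1/4 image height below centre of the y axis
    y_post = (nrows * h) / 4.0
    max_len = y_post - ys[2]  # keep a 2-pixel anterior margin

    tissue = np.full(shape, SOFT_TISSUE_HU)

    def rasterize(length: float) -> np.ndarray:
        u = (Y - (y_post - length)) / length
        inside = (u >= 0) & (u <= 1) & (np.abs(X) < _aperture_half_width(u, iad, bowing))
        return inside

    def area_of(length: float) -> float:
        return float(rasterize(length).sum()) * h * h

    if ga_target == 0 or int(round(ga_target / (h * h))) == 0:
        pixels = tissue
        roi = (1, nrows - 1, 1, ncols - 1)
        return GlottisImage(pixels=pixels, pixel_spacing=pixel_spacing, roi=roi)

    # analytic length for the continuous aperture, then refine against the raster
    analytic_len = ga_target / (iad / 2.0 + (4.0 / np.pi) * bowing * iad)
    target_px = int(round(ga_target / (h * h)))
    if (
        analytic_len > max_len
        or rasterize(max_len).sum() < target_px
    ):
        raise ValueError(
            f"ga_target {ga_target} mm^2 unachievable within image bounds"
        )

    # rasterized pixel count is a nondecreasing step function of length:
    # bisect for the largest length not exceeding the target count ...
    lo, hi = 1e-6, max_len
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if rasterize(mid).sum() > target_px:
            hi = mid
        else:
            lo = mid
    mask = rasterize(lo)

    # ... then top up pixel by pixel from the next-larger aperture's shell,
    # most-interior first, keeping 4-connectivity with the current component
    deficit = target_px - int(mask.sum())
    if deficit > 0:
        shell = rasterize(hi) & ~mask
        u = (Y - (y_post - hi)) / hi
        with np.errstate(invalid="ignore"):
            interiorness = np.where(
                shell, _aperture_half_width(np.clip(u, 0, 1), iad, bowing)
                - np.abs(X), -np.inf,
            )
        for _ in range(deficit):
            neighbours = np.zeros_like(mask)
            neighbours[1:, :] |= mask[:-1, :]
            neighbours[:-1, :] |= mask[1:, :]
            neighbours[:, 1:] |= mask[:, :-1]
            neighbours[:, :-1] |= mask[:, 1:]
            candidates = shell & ~mask & neighbours
            if not candidates.any():
                candidates = shell & ~mask
            score = np.where(candidates, interiorness, -np.inf)
            r, c = np.unravel_index(int(np.argmax(score)), score.shape)
            mask[r, c] = True
    pixels = tissue.copy()
    pixels[mask] = AIR_HU

    rows, cols = np.nonzero(mask)
    r0 = max(int(rows.min()) - 2, 0)
    r1 = min(int(rows.max()) + 3, nrows)
    c0 = max(int(cols.min()) - 2, 0)
    c1 = min(int(cols.max()) + 3, ncols)
    return GlottisImage(pixels=pixels, pixel_spacing=pixel_spacing, roi=(r0, r1, c0, c1))
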