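"""Elliptical annulus sector grid and regional thickness statistics.

The grid reproduces the Cirrus-style macular GCIPL chart: an elliptical
annulus about the fovea (vertical inner/outer radii 0.5/2.0 mm, horizontal
0.6/2.4 mm) divided into six 60-degree wedges of elliptically normalized
angle — superior nasal (SN), superior (S), superior temporal (ST), inferior
temporal (IT), inferior (I) and inferior nasal (IN).  S and I are centered
on the vertical meridian (S spans 60-120 degrees from the temporal
horizontal).

Conventions (fixed once for the whole package):

* pixel coordinates are 0-based ``(x, y)`` = (column, row); row 0 is the
  superior edge;
* maps are in right-eye (OD) orientation with the nasal side at +x; OS maps
  must be mirrored upstream (pass ``laterality="OS"`` only for maps still in
  as-acquired left-eye orientation);
* the elliptically normalized angle is computed on coordinates scaled by
  ``(1/h_outer, 1/v_outer)``, so wedge boundaries are straight lines through
  the fovea;
* pixels are assigned by center-of-pixel membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import (
    DEFAULT_ANNULUS,
    DEFAULT_GRID,
    INFERIOR_SECTORS,
    SECTORS,
    SUPERIOR_SECTORS,
    AnnulusGeometry,
    GridGeometry,
)

# wedge order by normalized-angle bin, starting at the temporal horizontal
# and proceeding through the superior hemifield (OD orientation)
_BIN_ORDER = ("ST", "S", "SN", "IN", "I", "IT")


@dataclass
class SectorMasks:
    """Boolean masks of the annulus and its six sectors on the map raster."""

    annulus: np.ndarray
    sectors: dict[str, np.ndarray]
    clipped: bool

    def __post_init__(self) -> None:
        assert set(self.sectors) == set(SECTORS)


@dataclass
class SectorProfile:
    """Mean thickness (um) of the annulus and its six sectors.

    ``annulus_mean`` is the pixel-count-weighted mean of the sector means
    (i.e. the arithmetic mean over all annulus pixels).  Sectors that lost
    all their pixels to image clipping carry NaN, never a silent zero.
    """

    annulus_mean: float
    sector_means: dict[str, float]
    pixel_counts: dict[str, int]
    clipped: bool = False

    @property
    def mean_of_sectors(self) -> float:
        """Unweighted mean of the six sector means (the Cirrus summary value)."""
        return float(np.mean([self.sector_means[s] for s in SECTORS]))

    def as_row(self) -> dict:
        row = {"annulus": self.annulus_mean}
        row.update({s: self.sector_means[s] for s in SECTORS})
        row["clipped_flag"] = int(self.clipped)
        return row


def _normalized_coords(shape, fovea_px, pitch_mm, geometry):
    ny, nx = shape
    fx, fy = fovea_px
    x_mm = (np.arange(nx) - fx) * pitch_mm
    y_mm = (np.arange(ny) - fy) * pitch_mm
    dx = np.broadcast_to(x_mm[None, :], shape)
    dy = np.broadcast_to(y_mm[:, None], shape)
    return dx, dy


def sector_masks(
    fovea_px,
    shape=None,
    pitch_mm: float | None = None,
    geometry: AnnulusGeometry = DEFAULT_ANNULUS,
    grid: GridGeometry = DEFAULT_GRID,
    laterality: str = "OD",
) -> SectorMasks:
    """Compute the annulus mask and the six disjoint sector masks.

    Parameters
    ----------
    fovea_px : (x, y) fovea position in pixels; must lie inside the image.
    shape, pitch_mm : raster shape and pixel pitch; default from ``grid``.
    laterality : "OD" (default) or "OS"; for OS the nasal/temporal wedge
        labels are swapped so labels remain anatomical.
    """
    if shape is None:
        shape = (grid.n_px, grid.n_px)
    if pitch_mm is None:
        pitch_mm = grid.extent_mm / shape[1]
    fx, fy = float(fovea_px[0]), float(fovea_px[1])
    ny, nx = shape
    if not (0 <= fx < nx and 0 <= fy < ny):
        raise ValueError(f"fovea {fovea_px} outside image of shape {shape}")
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")

    dx, dy = _normalized_coords(shape, (fx, fy), pitch_mm, geometry)
    r_out = np.hypot(dx / geometry.h_outer, dy / geometry.v_outer)
    r_in = np.hypot(dx / geometry.h_inner, dy / geometry.v_inner)
    annulus = (r_in >= 1.0) & (r_out <= 1.0)

    # outer ellipse clipped by the image border?
    clipped = (
        fx - geometry.h_outer / pitch_mm < -0.5
        or fx + geometry.h_outer / pitch_mm > nx - 0.5
        or fy - geometry.v_outer / pitch_mm < -0.5
        or fy + geometry.v_outer / pitch_mm > ny - 0.5
    )

    # elliptically normalized angle; temporal = -x for OD, +x for OS
    tx = -dx if laterality == "OD" else dx
    sup = -dy  # superior is up (row 0)
    theta = np.degrees(np.arctan2(sup / geometry.v_outer, tx / geometry.h_outer))
    bins = np.floor_divide(np.mod(theta, 360.0), 60.0).astype(int)
    bins = np.clip(bins, 0, 5)

    sectors = {
        label: annulus & (bins == k) for k, label in enumerate(_BIN_ORDER)
    }
    return SectorMasks(annulus=annulus, sectors=sectors, clipped=bool(clipped))


def sector_means(
    thickness_um: np.ndarray,
    fovea_px,
    pitch_mm: float | None = None,
    geometry: AnnulusGeometry = DEFAULT_ANNULUS,
    grid: GridGeometry = DEFAULT_GRID,
    laterality: str = "OD",
) -> SectorProfile:
    """Arithmetic mean thickness over the annulus and each sector."""
    thickness_um = np.asarray(thickness_um, dtype=float)
    if not np.all(np.isfinite(thickness_um)):
        raise ValueError("thickness map contains non-finite values")
    masks = sector_masks(
        fovea_px, shape=thickness_um.shape, pitch_mm=pitch_mm,
        geometry=geometry, grid=grid, laterality=laterality,
    )
    if masks.clipped:
        warnings.warn("annulus clipped by image border; profile flagged", stacklevel=2)
    means, counts = {}, {}
    for label, mask in masks.sectors.items():
        n = int(mask.sum())
        counts[label] = n
        means[label] = float(thickness_um[mask].mean()) if n else float("nan")
    n_total = int(masks.annulus.sum())
    annulus_mean = float(thickness_um[masks.annulus].mean()) if n_total else float("nan")
    counts["annulus"] = n_total
    return SectorProfile(
        annulus_mean=annulus_mean, sector_means=means,
        pixel_counts=counts, clipped=masks.clipped,
    )


def hemifield_ratios(profile: SectorProfile, reference_um: float) -> tuple[float, float]:
    """Pixel-weighted inferior and superior hemifield means over a reference.

    Returns ``(r_inf, r_sup)`` where each hemifield mean pools the three
    corresponding sectors weighted by pixel count.  These ratios anchor the
    display latents d1 (inferior) and d2 (superior).
    """
    if not reference_um > 0:
        raise ValueError("reference_um must be positive")

    def pooled(labels):
        w = np.array([profile.pixel_counts[s] for s in labels], dtype=float)
        m = np.array([profile.sector_means[s] for s in labels], dtype=float)
        if w.sum() == 0:
            return float("nan")
        return float(np.sum(w * m) / w.sum())

    return pooled(INFERIOR_SECTORS) / reference_um, pooled(SUPERIOR_SECTORS) / reference_um


def profiles_to_frame(profiles, keys=None):
    """Tabulate profiles as one row per map (annulus, SN..IN, clipped_flag)."""
    import pandas as pd

    rows = [p.as_row() for p in profiles]
    frame = pd.DataFrame(rows)
    if keys is not None:
        frame.insert(0, "key", list(keys))
    return frame
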