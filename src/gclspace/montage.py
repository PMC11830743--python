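"""Latent-space montage maps, normative KDE contours, longitudinal trajectories.

The montage tiles a rectangular (d1, d2) range (default (-5, -5) to (8, 4),
step 1) with display-decoder reconstructions, giving a visual atlas of
thinning patterns: inferior thinning upper-left, normal/thickening
upper-right, diffuse lower-left, superior lower-right.  Kernel density
contours of a reference (normative) cohort mark the normal range, and
per-eye visit trajectories can be overlaid to read progression off the map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

DAYS_PER_MONTH = 30.44


@dataclass
class ContourSet:
    """Iso-proportion KDE contours: polylines in (d1, d2) coordinates."""

    levels: tuple  # requested probability-mass levels
    polylines: dict  # level -> list of (k, 2) arrays
    densities: dict  # level -> density threshold
    bandwidth: tuple


@dataclass
class MontageMap:
    d1_values: np.ndarray
    d2_values: np.ndarray
    tiles: np.ndarray  # (n_d2, n_d1, h, w) um
    contours: ContourSet | None = None

    @property
    def grid_shape(self):
        return (len(self.d1_values), len(self.d2_values))


def _grid_1d(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    vals = lo + step * np.arange(n)
    if vals[-1] < hi - 1e-9:  # inclusive endpoint
        vals = np.append(vals, hi)
    return vals


def make_montage(
    model,
    d1_range=(-5.0, 8.0),
    d2_range=(-5.0, 4.0),
    step: float = 1.0,
    contours: ContourSet | None = None,
) -> MontageMap:
    """Decode one display-only tile per (d1, d2) grid node.

    The grid covers the range inclusively; d1 indexes the x-axis, d2 the
    y-axis.  Pure function of the checkpoint: repeated calls are identical.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    d1v = _grid_1d(*d1_range, step)
    d2v = _grid_1d(*d2_range, step)
    h = model.cfg.crop_px
    tiles = np.empty((len(d2v), len(d1v), h, h))
    for j, d2 in enumerate(d2v):
        for i, d1 in enumerate(d1v):
            tiles[j, i] = model.decode_display(np.array([d1, d2]))
    return MontageMap(d1_values=d1v, d2_values=d2v, tiles=tiles, contours=contours)


def kde_density_grid(points, grid_x, grid_y, bandwidth=None, bw_floor=1e-3):
    """Product-Gaussian KDE evaluated on a rectangular grid.

    Bandwidth defaults to Scott's rule per dimension, floored at
    ``bw_floor`` (degenerate point sets trigger the floor and a warning).
    """
    pts = np.asarray(points, float)
    n = pts.shape[0]
    if bandwidth is None:
        scott = n ** (-1.0 / 6.0)
        sd = pts.std(axis=0, ddof=1)
        if np.any(sd < bw_floor):
            warnings.warn("degenerate point set; bandwidth floor applied", stacklevel=2)
        bandwidth = tuple(np.maximum(sd * scott, bw_floor))
    bx, by = bandwidth
    gx = np.asarray(grid_x)[None, :]
    gy = np.asarray(grid_y)[None, :]
    kx = np.exp(-0.5 * ((gx - pts[:, :1]) / bx) ** 2) / (bx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy - pts[:, 1:2]) / by) ** 2) / (by * np.sqrt(2 * np.pi))
    # contract over points without forming the (n, ny, nx) intermediate
    density = np.einsum("ny,nx->yx", ky, kx) / pts.shape[0]
    return density, bandwidth


def kde_point_density(points, query, bandwidth, chunk: int = 512):
    pts = np.asarray(points, float)
    q = np.asarray(query, float)
    bx, by = bandwidth
    out = np.empty(q.shape[0])
    norm = 2 * np.pi * bx * by
    for lo in range(0, q.shape[0], chunk):
        qq = q[lo : lo + chunk]
        e = (
            -0.5 * ((qq[:, None, 0] - pts[None, :, 0]) / bx) ** 2
            - 0.5 * ((qq[:, None, 1] - pts[None, :, 1]) / by) ** 2
        )
        out[lo : lo + chunk] = np.exp(e).mean(axis=1) / norm
    return out


def kde_contours(
    points,
    levels=(0.25, 0.5, 0.75, 0.9),
    grid_n: int = 201,
    pad: float = 1.0,
    bandwidth=None,
) -> ContourSet:
    """Iso-proportion contours of a product-Gaussian KDE.

    A level of 0.5 is the highest-density region enclosing 50% of the
    probability mass.  Deterministic given points and bandwidth.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 10:
        raise ValueError("need at least 10 (d1, d2) points")
    from skimage import measure

    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    gx = np.linspace(lo[0], hi[0], grid_n)
    gy = np.linspace(lo[1], hi[1], grid_n)
    density, bw = kde_density_grid(pts, gx, gy, bandwidth=bandwidth)

    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    total = cum[-1]

    polylines, thresholds = {}, {}
    for level in levels:
        k = np.searchsorted(cum, level * total)
        thr = flat[min(k, flat.size - 1)]
        thresholds[level] = float(thr)
        lines = []
        for contour in measure.find_contours(density, thr):
            # rows index gy, cols index gx -> map to data coordinates
            xs = np.interp(contour[:, 1], np.arange(grid_n), gx)
            ys = np.interp(contour[:, 0], np.arange(grid_n), gy)
            lines.append(np.column_stack([xs, ys]))
        polylines[level] = lines
    return ContourSet(levels=tuple(levels), polylines=polylines,
                      densities=thresholds, bandwidth=tuple(bw))


def contour_coverage(points, contours: ContourSet, level: float) -> float:
    """Empirical fraction of points inside the given iso-proportion contour."""
    dens = kde_point_density(points, points, contours.bandwidth)
    return float(np.mean(dens >= contours.densities[level]))


@dataclass
class Trajectory:
    """Per-visit display-latent positions of one eye, in visit order."""

    d_points: np.ndarray  # (n_visits, 2)
    intervals_days: list
    label: str = ""

    def interval_months(self) -> list[str]:
        return [f"{d / DAYS_PER_MONTH:.1f} months" for d in self.intervals_days]


def trajectory_from_codes(codes, intervals_days, label="") -> Trajectory:
    d = np.array([c.d for c in codes], float)
    if len(intervals_days) != len(d) - 1:
        raise ValueError("intervals_days must have length n_visits - 1")
    return Trajectory(d_points=d, intervals_days=list(intervals_days), label=label)


# -- rendering -------------------------------------------------------------


def render_montage(
    montage: MontageMap,
    out_path=None,
    trajectories=(),
    vmax_um: float = 120.0,
    cmap: str = "turbo",
):
    """Render tiles (shared 0..vmax_um color scale), contours and
    trajectories into one matplotlib figure; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d1v, d2v = montage.d1_values, montage.d2_values
    step1 = d1v[1] - d1v[0] if len(d1v) > 1 else 1.0
    step2 = d2v[1] - d2v[0] if len(d2v) > 1 else 1.0
    h = montage.tiles.shape[-1]
    big = np.zeros((len(d2v) * h, len(d1v) * h))
    for j in range(len(d2v)):
        for i in range(len(d1v)):
            # low d2 at the bottom row of the image
            big[(len(d2v) - 1 - j) * h : (len(d2v) - j) * h, i * h : (i + 1) * h] = (
                montage.tiles[j, i]
            )
    extent = (
        d1v[0] - step1 / 2, d1v[-1] + step1 / 2,
        d2v[0] - step2 / 2, d2v[-1] + step2 / 2,
    )
    fig, ax = plt.subplots(figsize=(1.0 * len(d1v), 1.0 * len(d2v)))
    im = ax.imshow(big, origin="upper", extent=extent, vmin=0, vmax=vmax_um,
                   cmap=cmap, interpolation="nearest")
    if montage.contours is not None:
        for level, lines in montage.contours.polylines.items():
            for line in lines:
                ax.plot(line[:, 0], line[:, 1], color="blue", lw=1.2, alpha=0.8)
    for traj in trajectories:
        d = traj.d_points
        if len(d) == 1:
            ax.plot(d[0, 0], d[0, 1], "o", color="black")
        else:
            ax.plot(d[:, 0], d[:, 1], "-o", lw=1.5)
            for k, label in enumerate(traj.interval_months()):
                mid = (d[k] + d[k + 1]) / 2
                ax.annotate(label, mid, fontsize=7)
        if traj.label:
            ax.annotate(traj.label, d[0], fontsize=8, fontweight="bold")
    ax.set_xlabel("d1")
    ax.set_ylabel("d2")
    fig.colorbar(im, ax=ax, label="GCIPL thickness (um)", shrink=0.6)
    if out_path is not None:
        fig.savefig(out_path, dpi=110, bbox_inches="tight")
        plt.close(fig)
    return fig


def export_json(path, contours: ContourSet | None = None, trajectories=()):
    """Machine-readable contours and trajectory coordinates."""
    payload = {}
    if contours is not None:
        payload["contours"] = {
            str(level): [line.tolist() for line in lines]
            for level, lines in contours.polylines.items()
        }
        payload["bandwidth"] = list(contours.bandwidth)
    payload["trajectories"] = [
        {
            "label": t.label,
            "d_points": t.d_points.tolist(),
            "intervals_days": list(t.intervals_days),
            "interval_months": t.interval_months(),
        }
        for t in trajectories
    ]
    from pathlib import Path

    Path(path).write_text(json.dumps(payload, indent=2))
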