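"""Reading and writing thickness maps, manifests and run logs.

Supported map dialects:

* ``tiff16`` — 16-bit single-channel TIFF, 0.1 um per integer unit;
* ``array-archive`` — compressed ``.npz`` with keys ``values_um``,
  ``fovea_px``, ``laterality``, ``qc_good``;
* ``csv-grid`` — plain comma-separated grid of um values.

Maps are returned on the canonical 200 x 200 raster; other input sizes are
resized bilinearly with a logged note.  Non-finite pixels are filled by
nearest-neighbor and the map is flagged as QC-bad.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .config import DEFAULT_GRID
from .phantom import ThicknessMap

log = logging.getLogger("gclspace")

TIFF_SCALE = 10.0  # integer units per um (0.1 um quantization)
DIALECTS = ("tiff16", "array-archive", "csv-grid")


def resize_map(values_um: np.ndarray, n_px: int) -> np.ndarray:
    """Bilinear resize (anti-aliased when downsampling) preserving um scale."""
    if values_um.shape == (n_px, n_px):
        return values_um
    return _sk_resize(
        values_um, (n_px, n_px), order=1,
        anti_aliasing=values_um.shape[0] > n_px, preserve_range=True,
    )


def _fill_nonfinite(values: np.ndarray) -> tuple[np.ndarray, bool]:
    bad = ~np.isfinite(values)
    if not bad.any():
        return values, False
    if bad.all():
        raise ValueError("thickness map contains no finite pixels")
    idx = ndimage.distance_transform_edt(bad, return_distances=False, return_indices=True)
    return values[tuple(idx)], True


def write_thickness_map(path, tmap: ThicknessMap, dialect: str = None) -> None:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "tiff16":
        q = np.clip(np.round(tmap.values_um * TIFF_SCALE), 0, 65535).astype(np.uint16)
        meta = {
            "fovea_px": list(tmap.fovea_px),
            "laterality": tmap.laterality,
            "qc_good": tmap.qc_good,
            "um_per_unit": 1.0 / TIFF_SCALE,
        }
        tifffile.imwrite(path, q, description=json.dumps(meta))
    elif dialect == "array-archive":
        np.savez_compressed(
            path, values_um=tmap.values_um, fovea_px=np.asarray(tmap.fovea_px),
            laterality=np.asarray(tmap.laterality), qc_good=np.asarray(tmap.qc_good),
        )
    elif dialect == "csv-grid":
        np.savetxt(path, tmap.values_um, delimiter=",", fmt="%.4f")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff16"
    if suffix == ".npz":
        return "array-archive"
    if suffix in (".csv", ".txt"):
        return "csv-grid"
    raise ValueError(f"cannot infer map dialect from {path.name!r}")


def read_thickness_map(path, dialect: str = None, n_px: int = None) -> ThicknessMap:
    """Load a map and return it um-scaled on the canonical raster.

    OS maps are mirrored to right-eye orientation at load, so downstream
    code is single-convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    n_px = n_px or DEFAULT_GRID.n_px
    fovea = None
    laterality = "OD"
    qc_good = True

    if dialect == "tiff16":
        with tifffile.TiffFile(path) as tf:
            values = tf.asarray().astype(float) / TIFF_SCALE
            desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                fovea = tuple(meta.get("fovea_px", ())) or None
                laterality = meta.get("laterality", "OD")
                qc_good = bool(meta.get("qc_good", True))
            except (ValueError, TypeError):
                pass
    elif dialect == "array-archive":
        with np.load(path, allow_pickle=False) as z:
            values = np.asarray(z["values_um"], dtype=float)
            if "fovea_px" in z:
                fovea = tuple(float(v) for v in z["fovea_px"])
            if "laterality" in z:
                laterality = str(z["laterality"])
            if "qc_good" in z:
                qc_good = bool(z["qc_good"])
    elif dialect == "csv-grid":
        values = np.loadtxt(path, delimiter=",", dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if values.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {values.shape}")
    values, filled = _fill_nonfinite(values)
    if filled:
        log.warning("%s: non-finite pixels filled by nearest neighbor; flagged", path.name)
        qc_good = False
    if values.shape != (n_px, n_px):
        log.info("%s: resized %s -> (%d, %d)", path.name, values.shape, n_px, n_px)
        scale = n_px / values.shape[1]
        values = resize_map(values, n_px)
        if fovea is not None:
            fovea = (fovea[0] * scale, fovea[1] * scale)
    if fovea is None:
        c = (n_px - 1) / 2.0
        fovea = (c, c)
    tmap = ThicknessMap(values_um=values, fovea_px=fovea,
                        laterality=laterality, qc_good=qc_good)
    return tmap.to_od_orientation()


def read_manifest(path):
    import pandas as pd

    return pd.read_csv(path, keep_default_na=False)


def write_run_log(path, seed: int, cfg_hash: str, extra: dict = None) -> None:
    """Record enough provenance (seed, config hash, versions) to reproduce a run."""
    import sys

    import numpy
    import scipy

    from . import __version__

    payload = {
        "seed": seed,
        "config_hash": cfg_hash,
        "versions": {
            "gclspace": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
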