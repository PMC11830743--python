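"""Synthetic GCIPL thickness phantoms: single maps, longitudinal eye series, cohorts.

The phantom emulates the anatomy the encoder is meant to exploit: ganglion
cell somas and dendrites are densest 4-6 degrees from the fovea, so a
normal GCIPL thickness map shows an elliptical perifoveal annulus of peak
thickness.  Optic neuropathies thin this annulus with disease-specific
angular signatures — inferior-dominant in glaucoma, diffuse in optic
neuritis, superior-dominant in NAION (often preceded by transient
thickening from disc edema).  Map model, in elliptical-polar coordinates
(rho, theta) about the (possibly decentered) fovea:

    thickness = base_floor + annulus_peak * exp(-(rho - r0)^2 / (2 w^2)) * M(theta) + noise

where ``M = 1 - severity * w(theta)`` and ``w`` is a raised-cosine bump over
the affected hemifield (identically 1 for diffuse loss, 0 for normal eyes).
Noise is i.i.d. Gaussian per pixel followed by 1-px Gaussian smoothing,
mimicking the spatial correlation of segmentation error.  Artifacts
(epiretinal-membrane-like focal thickening; poor-quality dropout) are
applied last; all values are clipped to be non-negative.  OS eyes are
mirrored horizontally at generation, as acquired by the instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import (
    ARTIFACTS,
    DEFAULT_CALIBRATION,
    DEFAULT_GRID,
    DISEASE_LABELS,
    PATTERN_CLASSES,
    GridGeometry,
    PhantomCalibration,
)

__all__ = [
    "PhantomParams",
    "ThicknessMap",
    "EyeSeries",
    "ClassSpec",
    "make_gcipl_map",
    "make_eye_series",
    "make_cohort",
    "calibration_cohort_spec",
    "longitudinal_cohort_spec",
    "training_pool_spec",
    "normal_template",
]

# Calibrated per-disease severity Beta distributions (see docs/methods.md):
# means chosen so that 500-eye class cohorts land on the normative summary
# thicknesses of the emulated clinical populations.
CLASS_SEVERITY_BETA = {
    "glaucoma": (4.6068, 1.3932),  # mean 0.7678, inferior/superior-dominant loss
    "NAION": (2.3208, 3.6792),     # mean 0.3868, superior-dominant loss
    "ON": (1.1466, 4.8534),        # mean 0.1911, diffuse loss
}

DISEASE_PATTERNS = {
    "normal": {"normal": 1.0},
    "glaucoma": {"inferior": 0.85, "superior": 0.15},
    "ON": {"diffuse": 1.0},
    "NAION": {"superior": 1.0},
}


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters of one synthetic GCIPL map."""

    pattern_class: str = "normal"
    severity: float = 0.0
    base_floor_um: float = DEFAULT_CALIBRATION.base_floor_um
    annulus_peak_um: float = DEFAULT_CALIBRATION.annulus_peak_um
    ring_radius_mm: float = DEFAULT_CALIBRATION.ring_radius_mm
    ring_width_mm: float = DEFAULT_CALIBRATION.ring_width_mm
    fovea_offset_px: tuple[int, int] = (0, 0)
    noise_sd_um: float = DEFAULT_CALIBRATION.noise_sd_um
    artifact: str = "none"
    laterality: str = "OD"
    edema_scale: float = 1.0  # multiplies annulus_peak (transient disc-edema thickening)

    def __post_init__(self) -> None:
        if self.pattern_class not in PATTERN_CLASSES:
            raise ValueError(f"unknown pattern_class {self.pattern_class!r}")
        if self.artifact not in ARTIFACTS:
            raise ValueError(f"unknown artifact {self.artifact!r}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS")
        scalars = (
            self.severity, self.base_floor_um, self.annulus_peak_um,
            self.ring_radius_mm, self.ring_width_mm, self.noise_sd_um,
            self.edema_scale, *self.fovea_offset_px,
        )
        if not all(math.isfinite(v) for v in scalars):
            raise ValueError("non-finite phantom parameter")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if not 0.0 < self.ring_radius_mm <= 3.0:
            raise ValueError("ring_radius_mm must lie in (0, 3] mm")
        if self.noise_sd_um < 0:
            raise ValueError("noise_sd_um must be >= 0")


@dataclass
class ThicknessMap:
    """A GCIPL thickness map in um with its ground-truth annotations."""

    values_um: np.ndarray
    fovea_px: tuple[float, float]  # (x, y) in the stored orientation
    laterality: str = "OD"
    qc_good: bool = True

    @property
    def shape(self):
        return self.values_um.shape

    def to_od_orientation(self) -> "ThicknessMap":
        """Return a right-eye-orientation copy (mirrors OS maps)."""
        if self.laterality == "OD":
            return self
        n = self.values_um.shape[1]
        return ThicknessMap(
            values_um=self.values_um[:, ::-1].copy(),
            fovea_px=((n - 1) - self.fovea_px[0], self.fovea_px[1]),
            laterality="OD",
            qc_good=self.qc_good,
        )


@dataclass
class EyeSeries:
    """Ordered visits of one eye."""

    maps: list[ThicknessMap]
    intervals_days: list[int]
    progression_label: str  # beyond_normal_range | within_normal_range
    disease_label: str
    subject_id: str = ""
    eye: str = "OD"
    severities: list[float] = field(default_factory=list)
    pattern_class: str = "normal"

    def __post_init__(self) -> None:
        if len(self.intervals_days) != max(len(self.maps) - 1, 0):
            raise ValueError("intervals_days must have length n_visits - 1")

    @property
    def n_visits(self) -> int:
        return len(self.maps)

    @property
    def visit_days(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.intervals_days)]).astype(int)


def _angular_mask(u, v, pattern, severity, shoulder_deg):
    """M(theta) = 1 - severity * w(theta) on normalized coordinates (u, v)."""
    if pattern == "normal" or severity == 0.0:
        return 1.0
    if pattern == "diffuse":
        return 1.0 - severity
    # elevation from the horizontal meridian, folded into [0, 90] degrees
    a = np.degrees(np.arctan2(np.abs(v), np.abs(u)))
    ramp = np.where(
        a >= shoulder_deg, 1.0, 0.5 * (1.0 - np.cos(np.pi * a / shoulder_deg))
    )
    hemi = v > 0 if pattern == "inferior" else v < 0  # +v is inferior (row grows downward)
    return 1.0 - severity * ramp * hemi


def _render_noise(rng, shape, sd_um, smooth_px):
    if sd_um == 0:
        return 0.0
    raw = rng.normal(0.0, sd_um, size=shape)
    return gaussian_filter(raw, smooth_px, mode="nearest") if smooth_px > 0 else raw


def make_gcipl_map(
    params: PhantomParams,
    seed: int,
    grid: GridGeometry = DEFAULT_GRID,
    calibration: PhantomCalibration = DEFAULT_CALIBRATION,
) -> ThicknessMap:
    """Render one synthetic GCIPL thickness map.

    Identical ``(params, seed)`` produce bit-identical maps.  The map is
    rendered in right-eye orientation about ``center + fovea_offset_px`` and
    mirrored at the end for OS eyes.
    """
    rng = np.random.default_rng(seed)
    n = grid.n_px
    pitch = grid.pitch_mm
    cx, cy = grid.center_px
    fx = cx + params.fovea_offset_px[0]
    fy = cy + params.fovea_offset_px[1]

    x_mm = (np.arange(n) - fx) * pitch
    y_mm = (np.arange(n) - fy) * pitch
    dx = x_mm[None, :]
    dy = y_mm[:, None]
    u = np.broadcast_to(dx / calibration.aspect, (n, n))
    v = np.broadcast_to(dy, (n, n))
    rho = np.hypot(u, v)  # vertical-equivalent mm

    ring = np.exp(-((rho - params.ring_radius_mm) ** 2) / (2.0 * params.ring_width_mm**2))
    mask = _angular_mask(u, v, params.pattern_class, params.severity, calibration.shoulder_deg)
    values = (
        params.base_floor_um
        + params.annulus_peak_um * params.edema_scale * ring * mask
    )

    noise_sd = params.noise_sd_um
    values = values + _render_noise(rng, (n, n), noise_sd, calibration.noise_smooth_px)

    if params.artifact == "erm_focal_thickening":
        # focal thickening blob in the superior-temporal quadrant (temporal = -x in OD)
        jitter = rng.uniform(-0.3, 0.3, size=2)
        bx = -1.2 + jitter[0]
        by = -1.2 + jitter[1]
        values = values + calibration.erm_amp_um * np.exp(
            -((dx - bx) ** 2 + (dy - by) ** 2) / (2.0 * calibration.erm_sigma_mm**2)
        )
    elif params.artifact == "poor_quality":
        # extra noise (doubling the nominal sd) then a rectangular dropout to 0
        extra = _render_noise(
            rng, (n, n), noise_sd * math.sqrt(3.0), calibration.noise_smooth_px
        )
        values = values + extra
        frac = rng.uniform(0.15, 0.35)
        w_frac = min(1.0, math.sqrt(frac) * rng.uniform(0.8, 1.25))
        h_frac = min(1.0, frac / w_frac)
        w_px = max(1, int(round(w_frac * n)))
        h_px = max(1, int(round(h_frac * n)))
        r0 = int(rng.integers(0, n - h_px + 1))
        c0 = int(rng.integers(0, n - w_px + 1))
        values[r0 : r0 + h_px, c0 : c0 + w_px] = 0.0

    values = np.clip(values, 0.0, None)

    if params.laterality == "OS":
        values = values[:, ::-1].copy()
        fx = (n - 1) - fx

    return ThicknessMap(
        values_um=values,
        fovea_px=(fx, fy),
        laterality=params.laterality,
        qc_good=params.artifact != "poor_quality",
    )


def normal_template(
    grid: GridGeometry = DEFAULT_GRID,
    calibration: PhantomCalibration = DEFAULT_CALIBRATION,
) -> ThicknessMap:
    """The noise-free normal phantom at default calibration."""
    return make_gcipl_map(PhantomParams(noise_sd_um=0.0), seed=0, grid=grid,
                          calibration=calibration)


def make_eye_series(
    initial: PhantomParams,
    n_visits: int,
    progression_rate: float,
    seed: int,
    intervals_days=None,
    disease_label: str = "normal",
    subject_id: str = "",
    edema_baseline: bool = False,
    edema_scale: float = 1.25,
    threshold: float | None = None,
    grid: GridGeometry = DEFAULT_GRID,
    calibration: PhantomCalibration = DEFAULT_CALIBRATION,
) -> EyeSeries:
    """Generate an ordered visit series with linearly progressing severity.

    Visit ``k`` has severity ``min(1, severity0 + k * progression_rate)``.
    The eye is labeled ``beyond_normal_range`` iff the final severity exceeds
    the configured normal-band threshold.  With ``edema_baseline`` the first
    visit inflates the annulus peak (NAION-style transient thickening).
    """
    if n_visits < 1:
        raise ValueError("n_visits must be >= 1")
    if progression_rate < 0:
        raise ValueError("progression_rate must be >= 0")
    if threshold is None:
        threshold = calibration.normal_band_threshold
    rng = np.random.default_rng(seed)
    visit_seeds = rng.integers(0, 2**31, size=n_visits)
    if intervals_days is None:
        intervals_days = [int(d) for d in rng.integers(60, 366, size=max(n_visits - 1, 0))]
    else:
        intervals_days = [int(d) for d in intervals_days]
        if len(intervals_days) != n_visits - 1:
            raise ValueError("intervals_days must have length n_visits - 1")
        if any(d <= 0 for d in intervals_days):
            raise ValueError("intervals_days must be positive")

    severities = [min(1.0, initial.severity + k * progression_rate) for k in range(n_visits)]
    maps = []
    for k, (sev, vseed) in enumerate(zip(severities, visit_seeds)):
        p = replace(
            initial,
            severity=sev,
            edema_scale=edema_scale if (edema_baseline and k == 0) else 1.0,
        )
        maps.append(make_gcipl_map(p, int(vseed), grid=grid, calibration=calibration))

    label = "beyond_normal_range" if severities[-1] > threshold else "within_normal_range"
    return EyeSeries(
        maps=maps,
        intervals_days=intervals_days,
        progression_label=label,
        disease_label=disease_label,
        subject_id=subject_id,
        eye=initial.laterality,
        severities=severities,
        pattern_class=initial.pattern_class,
    )


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassSpec:
    """Per-disease sampling distributions used by :func:`make_cohort`."""

    n_eyes: int
    patterns: dict  # pattern_class -> probability
    severity_beta: tuple[float, float] | None = None  # None -> severity 0
    n_visits: tuple[int, int] = (1, 1)
    progression_rate: tuple[float, float] = (0.0, 0.0)
    interval_days: tuple[int, int] = (60, 365)
    edema_prob: float = 0.0
    erm_rate: float = 0.0
    poor_rate: float = 0.0
    fovea_offset_max_px: int = 15
    floor_jitter_sd_um: float = 4.0
    peak_jitter_sd_um: float = 2.0
    ring_radius_jitter_mm: float = 0.04
    ring_width_jitter_mm: float = 0.03

    def __post_init__(self) -> None:
        if self.n_eyes < 0:
            raise ValueError("n_eyes must be >= 0")


def calibration_cohort_spec(n_per_class: int = 500) -> dict:
    """Cross-sectional (single-visit) cohorts at the default calibration.

    Class severity distributions are the calibrated Beta laws; artifact
    rates are zero so the cohorts consist of QC-good scans, matching how
    normative summary thicknesses are tabulated.
    """
    spec = {}
    for disease in DISEASE_LABELS:
        spec[disease] = ClassSpec(
            n_eyes=n_per_class,
            patterns=DISEASE_PATTERNS[disease],
            severity_beta=CLASS_SEVERITY_BETA.get(disease),
        )
    return spec


def longitudinal_cohort_spec(n_per_class: int = 60) -> dict:
    """Longitudinal cohorts (>= 3 visits) for progression classification."""
    spec = {}
    spec["normal"] = ClassSpec(
        n_eyes=n_per_class, patterns={"normal": 1.0},
        n_visits=(3, 6), erm_rate=0.02, poor_rate=0.03,
    )
    common = dict(n_visits=(3, 6), poor_rate=0.03)
    spec["glaucoma"] = ClassSpec(
        n_eyes=n_per_class, patterns=DISEASE_PATTERNS["glaucoma"],
        severity_beta=(1.3, 6.0), progression_rate=(0.0, 0.22),
        interval_days=(120, 420), erm_rate=0.15, **common,
    )
    spec["ON"] = ClassSpec(
        n_eyes=n_per_class, patterns=DISEASE_PATTERNS["ON"],
        severity_beta=(1.3, 6.0), progression_rate=(0.0, 0.22),
        interval_days=(120, 420), erm_rate=0.02, **common,
    )
    spec["NAION"] = ClassSpec(
        n_eyes=n_per_class, patterns=DISEASE_PATTERNS["NAION"],
        severity_beta=(1.3, 6.0), progression_rate=(0.0, 0.22),
        interval_days=(45, 120), edema_prob=0.6, erm_rate=0.02, **common,
    )
    return spec


def training_pool_spec(n_maps: int = 2000) -> dict:
    """Single-visit pool spanning the severity range, for VAE training.

    Severities are near-uniform so the display latents see the whole
    transition from normal to end-stage thinning; fovea decentration spans
    +/-20 px and both artifact types occur at realistic rates.
    """
    n_class = n_maps // 4
    spec = {}
    for disease in DISEASE_LABELS:
        spec[disease] = ClassSpec(
            n_eyes=n_class + (n_maps - 4 * n_class if disease == "normal" else 0),
            patterns=DISEASE_PATTERNS[disease],
            severity_beta=None if disease == "normal" else (1.0, 1.0),
            erm_rate=0.05,
            poor_rate=0.08,
            fovea_offset_max_px=20,
        )
    return spec


def _sample_params(rng, disease: str, cspec: ClassSpec) -> tuple[PhantomParams, dict]:
    patterns = list(cspec.patterns)
    probs = np.array([cspec.patterns[p] for p in patterns], dtype=float)
    pattern = patterns[rng.choice(len(patterns), p=probs / probs.sum())]
    if cspec.severity_beta is None or pattern == "normal":
        severity = 0.0
    else:
        a, b = cspec.severity_beta
        severity = float(rng.beta(a, b))
    u = rng.uniform()
    if u < cspec.poor_rate:
        artifact = "poor_quality"
    elif u < cspec.poor_rate + cspec.erm_rate:
        artifact = "erm_focal_thickening"
    else:
        artifact = "none"
    off = cspec.fovea_offset_max_px
    params = PhantomParams(
        pattern_class=pattern,
        severity=severity,
        base_floor_um=DEFAULT_CALIBRATION.base_floor_um
        + float(rng.normal(0.0, cspec.floor_jitter_sd_um)),
        annulus_peak_um=DEFAULT_CALIBRATION.annulus_peak_um
        + float(rng.normal(0.0, cspec.peak_jitter_sd_um)),
        ring_radius_mm=DEFAULT_CALIBRATION.ring_radius_mm
        + float(rng.normal(0.0, cspec.ring_radius_jitter_mm)),
        ring_width_mm=DEFAULT_CALIBRATION.ring_width_mm
        + float(rng.normal(0.0, cspec.ring_width_jitter_mm)),
        fovea_offset_px=(int(rng.integers(-off, off + 1)), int(rng.integers(-off, off + 1))),
        artifact=artifact,
        laterality="OD" if rng.uniform() < 0.5 else "OS",
    )
    extras = {
        "edema": bool(rng.uniform() < cspec.edema_prob),
        "rate": float(rng.uniform(*cspec.progression_rate)),
        "n_visits": int(rng.integers(cspec.n_visits[0], cspec.n_visits[1] + 1)),
        "intervals": cspec.interval_days,
    }
    return params, extras


def make_cohort(spec: dict, seed: int, out_dir=None,
                grid: GridGeometry = DEFAULT_GRID,
                calibration: PhantomCalibration = DEFAULT_CALIBRATION):
    """Generate class-conditional eye series and a manifest.

    Parameters
    ----------
    spec : mapping disease_label -> :class:`ClassSpec`.
    out_dir : if given, maps are written as 16-bit TIFFs there and the
        manifest ``path`` column points at them.

    Returns
    -------
    (series_list, manifest) where manifest is a pandas DataFrame with one
    row per visit.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    series_list: list[EyeSeries] = []
    rows = []
    if out_dir is not None:
        from . import io as _io
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    for disease in sorted(spec):
        cspec = spec[disease]
        for i in range(cspec.n_eyes):
            params, extras = _sample_params(rng, disease, cspec)
            intervals = [
                int(d)
                for d in rng.integers(
                    extras["intervals"][0], extras["intervals"][1] + 1,
                    size=max(extras["n_visits"] - 1, 0),
                )
            ]
            sid = f"{disease}_{i:04d}"
            eye_seed = int(rng.integers(0, 2**31))
            series = make_eye_series(
                params,
                n_visits=extras["n_visits"],
                progression_rate=extras["rate"],
                seed=eye_seed,
                intervals_days=intervals,
                disease_label=disease,
                subject_id=sid,
                edema_baseline=extras["edema"],
                grid=grid,
                calibration=calibration,
            )
            series_list.append(series)
            for k, tmap in enumerate(series.maps):
                path = ""
                if out_dir is not None:
                    # stored relative to the manifest so cohorts are relocatable
                    path = f"{sid}_v{k}.tif"
                    _io.write_thickness_map(out_dir / path, tmap)
                rows.append(
                    {
                        "subject_id": sid,
                        "eye": series.eye,
                        "visit_idx": k,
                        "interval_days": 0 if k == 0 else series.intervals_days[k - 1],
                        "disease_label": disease,
                        "progression_label": series.progression_label,
                        "qc_label": "good" if tmap.qc_good else "bad",
                        "fovea_x_px": tmap.fovea_px[0],
                        "fovea_y_px": tmap.fovea_px[1],
                        "path": path,
                    }
                )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "eye", "visit_idx", "interval_days", "disease_label",
            "progression_label", "qc_label", "fovea_x_px", "fovea_y_px", "path",
        ],
    )
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return series_list, manifest
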