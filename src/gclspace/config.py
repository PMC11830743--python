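"""Shared configuration: grid geometry, phantom calibration, model and training defaults.

All length constants are millimetres unless suffixed ``_um`` (micrometres,
thickness) or ``_px`` (pixels).  The canonical raster is 200 x 200 px over
6 x 6 mm (0.03 mm/px), matching Cirrus-style macular GCIPL thickness maps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

SECTORS = ("SN", "S", "ST", "IT", "I", "IN")
SUPERIOR_SECTORS = ("SN", "S", "ST")
INFERIOR_SECTORS = ("IT", "I", "IN")

PATTERN_CLASSES = ("normal", "inferior", "diffuse", "superior")
DISEASE_LABELS = ("normal", "glaucoma", "ON", "NAION")
ARTIFACTS = ("none", "erm_focal_thickening", "poor_quality")


@dataclass(frozen=True)
class GridGeometry:
    """Raster geometry of a thickness map."""

    n_px: int = 200
    extent_mm: float = 6.0

    @property
    def pitch_mm(self) -> float:
        return self.extent_mm / self.n_px

    @property
    def center_px(self) -> tuple[float, float]:
        # (x, y), 0-based pixel-center coordinates
        c = (self.n_px - 1) / 2.0
        return (c, c)


DEFAULT_GRID = GridGeometry()


@dataclass(frozen=True)
class AnnulusGeometry:
    """Cirrus-equivalent elliptical annulus: vertical radii 0.5/2.0 mm,
    horizontal radii 0.6/2.4 mm, divided into six sectors."""

    v_inner: float = 0.5
    v_outer: float = 2.0
    h_inner: float = 0.6
    h_outer: float = 2.4

    def __post_init__(self) -> None:
        if not (self.v_inner < self.v_outer and self.h_inner < self.h_outer):
            raise ValueError("inner radii must be smaller than outer radii")


DEFAULT_ANNULUS = AnnulusGeometry()


# --------------------------------------------------------------------------
# Phantom calibration
#
# The noise-free normal template is
#   thickness = base_floor + annulus_peak * exp(-(rho - ring_radius)^2 / (2 ring_width^2))
# in elliptical-polar coordinates with horizontal/vertical aspect 1.2 (the
# annulus grid aspect), rho expressed in vertical-equivalent mm.  The peak
# amplitude is chosen so that the six-sector annulus mean of the template
# equals the normative cohort mean thickness; class severity distributions
# are chosen so class cohort means land on their respective targets.
# Constants below are frozen by scripts in the repository history; they are
# configuration, not fitted at run time.
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomCalibration:
    base_floor_um: float = 40.0
    annulus_peak_um: float = 53.3647  # normal template six-sector mean = 78.68 um
    ring_radius_mm: float = 1.15  # vertical-equivalent eccentricity of the crest
    ring_width_mm: float = 0.55
    aspect: float = 1.2  # horizontal/vertical scaling of the annulus pattern
    noise_sd_um: float = 3.0  # pre-smoothing i.i.d. pixel noise
    noise_smooth_px: float = 1.0
    shoulder_deg: float = 20.0  # raised-cosine shoulder width of the hemifield bump
    erm_amp_um: float = 30.0
    erm_sigma_mm: float = 0.5
    normal_band_threshold: float = 0.2  # severity above which an eye is "beyond normal range"


DEFAULT_CALIBRATION = PhantomCalibration()


@dataclass(frozen=True)
class AnchorMap:
    """Affine map t(r) = scale * (r - offset) sending a hemifield thickness
    ratio to its display-latent anchor; reference_um normalizes the ratio."""

    reference_um: float = 80.0
    scale: float = 10.0
    offset: float = 0.8

    def __call__(self, ratio):
        return self.scale * (ratio - self.offset)


DEFAULT_ANCHOR = AnchorMap()


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and loss configuration of the booster VAE."""

    image_px: int = 200
    crop_px: int = 160
    n_display: int = 2
    n_booster: int = 8
    channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    dense_units: int = 256
    norm_um: float = 150.0  # thickness normalization divisor
    norm_clip: float = 1.3
    # loss weights
    w_recon_display: float = 1.0
    w_recon_full: float = 1.0
    w_kl_d: float = 1e-3
    w_kl_b: float = 1e-4
    w_anat: float = 0.5
    w_fovea: float = 2.0
    w_exclude: float = 0.1
    dtype: str = "float32"

    def scaled(self, image_px: int, crop_px: int, channels, dense_units: int) -> "ModelConfig":
        return dataclasses.replace(
            self, image_px=image_px, crop_px=crop_px,
            channels=tuple(channels), dense_units=dense_units,
        )


# Reduced-resolution configuration used by the reference (test) harness:
# 64 x 64 inputs, 48 x 48 fovea-centered crops, three residual stages.
HARNESS_MODEL = ModelConfig(
    image_px=64, crop_px=48, channels=(4, 8, 16), dense_units=80,
)


@dataclass(frozen=True)
class TrainConfig:
    epochs_max: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 8
    val_fraction: float = 0.15
    seed: int = 0
    split_salt: str = "gclspace-split-v1"


def config_to_yaml(cfg) -> str:
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)


def config_from_yaml(text: str, cls):
    data = yaml.safe_load(text) or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


def config_hash(cfg) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
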