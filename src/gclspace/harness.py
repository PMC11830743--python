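"""Reference end-to-end pipeline on reduced-resolution phantoms.

The harness is the package's standard seeded experiment: a 2000-map
training pool rendered at the canonical 200 x 200 resolution, downsampled
to 64 x 64 for CPU-scale training of a slim booster VAE, followed by the
evaluation cohorts used for latent-organization, fovea, QC, reconstruction
and classification checks.  All randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import annulus, io, phantom
from .config import (
    DEFAULT_ANCHOR,
    DEFAULT_GRID,
    HARNESS_MODEL,
    ModelConfig,
    TrainConfig,
)
from .model import BoosterVAE
from .train import TrainData, train

HARNESS_PX = HARNESS_MODEL.image_px
_SCALE = HARNESS_PX / DEFAULT_GRID.n_px


def map_to_harness(tmap: phantom.ThicknessMap) -> tuple[np.ndarray, tuple[float, float]]:
    """OD-orient and downsample one map to harness resolution; returns
    (values_um, fovea_px) in harness pixels."""
    od = tmap.to_od_orientation()
    values = io.resize_map(od.values_um, HARNESS_PX)
    # pixel-center convention: x' = (x + 0.5) * scale - 0.5
    fovea = (
        (od.fovea_px[0] + 0.5) * _SCALE - 0.5,
        (od.fovea_px[1] + 0.5) * _SCALE - 0.5,
    )
    return values, fovea


def anchors_for(values_um: np.ndarray, fovea_px, anchor=DEFAULT_ANCHOR) -> tuple[float, float]:
    """Anatomical anchor targets t(r_inf), t(r_sup) from the true fovea.

    Strongly decentered foveae clip the annulus by a sliver at harness
    resolution; the profile warning is expected there and suppressed.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        prof = annulus.sector_means(
            values_um, fovea_px, pitch_mm=DEFAULT_GRID.extent_mm / values_um.shape[0]
        )
    r_inf, r_sup = annulus.hemifield_ratios(prof, anchor.reference_um)
    return float(anchor(r_inf)), float(anchor(r_sup))


def build_train_data(series_list) -> TrainData:
    """Flatten eye series into harness-resolution training arrays."""
    maps, fovea, anchors, qc_bad, sids = [], [], [], [], []
    for s in series_list:
        for tmap in s.maps:
            values, fov = map_to_harness(tmap)
            maps.append(values)
            fovea.append(fov)
            qc_bad.append(not tmap.qc_good)
            anchors.append(anchors_for(values, fov))
            sids.append(s.subject_id)
    return TrainData(
        maps_um=np.stack(maps),
        fovea_px=np.asarray(fovea, float),
        anchors=np.asarray(anchors, float),
        qc_bad=np.asarray(qc_bad, bool),
        subject_ids=sids,
    )


def harness_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(epochs_max=40, batch_size=64, learning_rate=1e-3,
                       patience=8, val_fraction=0.15, seed=seed)


def train_harness_model(
    seed: int = 0,
    n_maps: int = 2000,
    model_cfg: ModelConfig = HARNESS_MODEL,
    train_cfg: TrainConfig | None = None,
):
    """Generate the training pool and train the harness model.

    Returns (model, history, train_data).
    """
    spec = phantom.training_pool_spec(n_maps)
    series, _ = phantom.make_cohort(spec, seed=seed)
    data = build_train_data(series)
    cfg = train_cfg or harness_train_config(seed)
    model, history = train(data, model_cfg, cfg)
    return model, history, data


# -- evaluation cohorts ----------------------------------------------------


@dataclass
class EvalPhantom:
    values_um: np.ndarray  # harness resolution, OD orientation
    fovea_px: tuple[float, float]
    pattern: str
    severity: float
    qc_good: bool


def make_eval_phantoms(
    seed: int,
    n: int,
    patterns=("normal", "inferior", "diffuse", "superior"),
    severity_range=(0.7, 1.0),
    offset_max_px: int = 15,
    poor_rate: float = 0.0,
) -> list[EvalPhantom]:
    """Held-out single-map phantoms at harness resolution.

    Diseased patterns draw severity from ``severity_range``; normals have
    severity 0.  Subject-independent of the training pool by construction
    (fresh parameter draws from a dedicated seed stream).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pattern = patterns[i % len(patterns)]
        severity = 0.0 if pattern == "normal" else float(rng.uniform(*severity_range))
        artifact = "poor_quality" if rng.uniform() < poor_rate else "none"
        params = phantom.PhantomParams(
            pattern_class=pattern,
            severity=severity,
            base_floor_um=phantom.DEFAULT_CALIBRATION.base_floor_um + rng.normal(0, 4.0),
            annulus_peak_um=phantom.DEFAULT_CALIBRATION.annulus_peak_um + rng.normal(0, 2.0),
            fovea_offset_px=(
                int(rng.integers(-offset_max_px, offset_max_px + 1)),
                int(rng.integers(-offset_max_px, offset_max_px + 1)),
            ),
            artifact=artifact,
        )
        tmap = phantom.make_gcipl_map(params, seed=int(rng.integers(0, 2**31)))
        values, fov = map_to_harness(tmap)
        out.append(EvalPhantom(values, fov, pattern, severity, tmap.qc_good))
    return out


def encode_eval_phantoms(model: BoosterVAE, phantoms) -> list:
    return model.encode_batch(np.stack([p.values_um for p in phantoms]))


def quadrant_accuracy(codes, patterns) -> float:
    """Fraction of phantoms whose (d1, d2) lands in the correct latent-space
    quadrant relative to the cohort component-wise medians: inferior ->
    upper-left, normal -> upper-right, diffuse -> lower-left, superior ->
    lower-right (d1 on x, d2 on y)."""
    d = np.array([c.d for c in codes])
    med = np.median(d, axis=0)
    expected = {
        "inferior": (-1, +1), "normal": (+1, +1),
        "diffuse": (-1, -1), "superior": (+1, -1),
    }
    ok = 0
    for (d1, d2), pattern in zip(d, patterns):
        e1, e2 = expected[pattern]
        ok += (np.sign(d1 - med[0]) == e1) and (np.sign(d2 - med[1]) == e2)
    return ok / len(patterns)


def severity_sweep_codes(model: BoosterVAE, pattern: str, seed: int, n: int = 40):
    """Encode a severity sweep of one pattern; returns (severities, codes)."""
    rng = np.random.default_rng(seed)
    severities = np.linspace(0.0, 1.0, n)
    maps = []
    for s in severities:
        params = phantom.PhantomParams(pattern_class=pattern, severity=float(s))
        tmap = phantom.make_gcipl_map(params, seed=int(rng.integers(0, 2**31)))
        maps.append(map_to_harness(tmap)[0])
    return severities, model.encode_batch(np.stack(maps))


# -- longitudinal classification harness -----------------------------------


def encode_series(model: BoosterVAE, series) -> list:
    """Latent codes for every visit of one eye, at harness resolution."""
    values = [map_to_harness(tmap)[0] for tmap in series.maps]
    return model.encode_batch(np.stack(values))


def longitudinal_feature_rows(model: BoosterVAE, series_list, use_blvs: bool):
    """Assemble three-time-point feature rows for a longitudinal cohort.

    QC-failed visits are dropped before visit selection (an eye needs at
    least 3 usable visits to contribute); the multiclass label is the
    disease for eyes that progressed beyond the normal range and
    ``within_normal_range`` otherwise.
    """
    import dataclasses as _dc

    from . import classify as cf

    rows_binary, rows_multi = [], []
    for s in series_list:
        codes = encode_series(model, s)
        usable = [k for k, tmap in enumerate(s.maps) if tmap.qc_good]
        if len(usable) < 3:
            continue
        days = s.visit_days[usable]
        i1, i2, i3 = cf.select_three_visits(days)
        picks = [usable[i] for i in (i1, i2, i3)]
        feats = np.concatenate(
            [codes[i].full if use_blvs else codes[i].d for i in picks]
        )
        eye_id = f"{s.subject_id}:{s.eye}"
        rows_binary.append(cf.FeatureRow(
            eye_id=eye_id, features=feats, label=s.progression_label,
            subject_id=s.subject_id, visit_indices=tuple(picks),
        ))
        multi_label = (
            s.disease_label if s.progression_label == "beyond_normal_range"
            else "within_normal_range"
        )
        rows_multi.append(_dc.replace(rows_binary[-1], label=multi_label))
    return rows_binary, rows_multi
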