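"""Training loop with subject-level splitting and validation early stopping."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig, TrainConfig
from .model import BoosterVAE

log = logging.getLogger("gclspace")

LOSS_KEYS = (
    "recon_display", "recon_full", "kl_d", "kl_b",
    "anat_d1", "anat_d2", "fovea_loss", "exclude_loss", "total",
)


@dataclass
class TrainData:
    """Flat training arrays: one entry per map.

    ``fovea_px`` is (x, y) in model-input pixels; ``anchors`` are the
    anatomical targets t(r_inf), t(r_sup) computed from the true fovea
    sector profile of each map; maps must already be in right-eye
    orientation at model resolution.
    """

    maps_um: np.ndarray          # (N, H, W)
    fovea_px: np.ndarray         # (N, 2)
    anchors: np.ndarray          # (N, 2)
    qc_bad: np.ndarray           # (N,) bool
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        n = self.maps_um.shape[0]
        assert self.fovea_px.shape == (n, 2)
        assert self.anchors.shape == (n, 2)
        assert self.qc_bad.shape == (n,)
        assert len(self.subject_ids) == n

    def __len__(self):
        return self.maps_um.shape[0]


def subject_split(subject_ids, val_fraction: float, salt: str) -> np.ndarray:
    """Deterministic subject-level split: True = validation member.

    No subject ever appears in both splits; membership is decided by a
    salted hash of the subject id, so it is stable across runs and cohorts.
    """
    out = np.zeros(len(subject_ids), dtype=bool)
    for i, sid in enumerate(subject_ids):
        h = hashlib.md5(f"{salt}:{sid}".encode()).hexdigest()
        out[i] = (int(h[:8], 16) % 10_000) < val_fraction * 10_000
    return out


def _crop_batch(model: BoosterVAE, maps_um, fovea_px):
    from .model import fovea_crop

    crops = np.stack(
        [fovea_crop(m, f, model.cfg.crop_px) for m, f in zip(maps_um, fovea_px)]
    )
    return model.normalize(crops)


def _run_batches(model, data, idx, batch_size, rng, optimizer=None):
    """One pass over ``idx``; returns mean loss components. With an optimizer
    this is a training pass (reparameterized sampling + updates)."""
    sums = {k: 0.0 for k in LOSS_KEYS}
    n_batches = 0
    for lo in range(0, len(idx), batch_size):
        sel = idx[lo : lo + batch_size]
        x = model.normalize(data.maps_um[sel])
        out = model.forward(x, rng=rng if optimizer is not None else None)
        bundle = model.compute_losses(
            out,
            _crop_batch(model, data.maps_um[sel], data.fovea_px[sel]),
            data.anchors[sel],
            data.fovea_px[sel] / model.cfg.image_px,
            data.qc_bad[sel],
        )
        if optimizer is not None:
            optimizer.zero_grad()
            bundle.total_tensor.backward()
            optimizer.step()
        for k in LOSS_KEYS:
            sums[k] += getattr(bundle, k)
        n_batches += 1
    return {k: v / max(n_batches, 1) for k, v in sums.items()}


def train(
    data: TrainData,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig = TrainConfig(),
) -> tuple[BoosterVAE, pd.DataFrame]:
    """Train a booster VAE with validation-based early stopping.

    Stops once the validation total loss has failed to improve for more
    than ``patience`` consecutive epochs, then restores the
    best-validation weights.  A non-finite loss aborts training and the
    best weights seen so far are retained.
    """
    if len(data) == 0:
        raise ValueError("empty training data")
    from .nn import Adam

    model = BoosterVAE(model_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng(train_cfg.seed + 1)
    val_mask = subject_split(data.subject_ids, train_cfg.val_fraction, train_cfg.split_salt)
    train_idx = np.flatnonzero(~val_mask)
    val_idx = np.flatnonzero(val_mask)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("subject split produced an empty partition")

    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    best_val = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    since_improve = 0
    rows = []
    aborted = False

    for epoch in range(train_cfg.epochs_max):
        order = train_idx.copy()
        rng.shuffle(order)
        try:
            tr = _run_batches(model, data, order, train_cfg.batch_size, rng, optimizer=opt)
            va = _run_batches(model, data, val_idx, train_cfg.batch_size, rng)
        except FloatingPointError as err:
            log.error("aborting at epoch %d: %s; best checkpoint retained", epoch, err)
            aborted = True
            break
        row = {"epoch": epoch}
        row.update({f"train_{k}": v for k, v in tr.items()})
        row.update({f"val_{k}": v for k, v in va.items()})
        rows.append(row)
        log.info("epoch %d: train %.5f val %.5f", epoch, tr["total"], va["total"])
        if va["total"] < best_val - 1e-7:
            best_val = va["total"]
            best_state = [a.copy() for a in model.state_arrays()]
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > train_cfg.patience:
                break

    model.load_state_arrays(best_state)
    if not aborted:
        _calibrate_fovea_bias(model, data, val_idx, train_cfg.batch_size)
    history = pd.DataFrame(rows)
    history.attrs["best_val_total"] = best_val
    history.attrs["aborted"] = aborted
    history.attrs["fovea_bias_px"] = tuple(model.fovea_bias_px)
    return model, history


def _calibrate_fovea_bias(model, data, val_idx, batch_size):
    """Estimate the mean signed fovea error on QC-good validation maps and
    store it so inference subtracts it (validation-calibrated correction;
    Adam leaves a slow-decaying residual output bias here)."""
    errs = []
    for lo in range(0, len(val_idx), batch_size):
        sel = val_idx[lo : lo + batch_size]
        good = ~data.qc_bad[sel]
        if not good.any():
            continue
        out = model.forward(model.normalize(data.maps_um[sel]))
        pred = out["fovea"].data * model.cfg.image_px
        errs.append(pred[good] - data.fovea_px[sel][good])
    if errs:
        model.fovea_bias_px = np.concatenate(errs).mean(axis=0)
        log.info("fovea bias calibration: %s px", np.round(model.fovea_bias_px, 3))
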