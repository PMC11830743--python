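"""The booster VAE: encoder, display decoder, booster decoder, loss terms.

The encoder decomposes a GCIPL thickness map into two display latents
(d1, d2), eight booster latents (b1..b8), an estimated fovea position and a
poor-quality exclusion probability.  The display decoder reconstructs a
fovea-centered crop of the input from the display latents alone (y_D); the
booster decoder, conditioned on all ten latents, adds a residual (y_B) so
that the full reconstruction is exactly y = y_D + y_B.  The two decoders
are co-trained but share no parameters.

Display latents are anatomically anchored: alongside a weak KL pull toward
the unit Gaussian, d1 and d2 are penalized toward affine transforms of the
inferior and superior hemifield thickness ratios, which organizes the
latent plane into quadrants — inferior thinning upper-left, normal (and
thickening) upper-right, diffuse thinning lower-left, superior thinning
lower-right.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .config import AnchorMap, DEFAULT_ANCHOR, ModelConfig, config_from_yaml, config_to_yaml
from .nn import Tensor

__all__ = [
    "LatentCode", "ReconPair", "LossBundle", "BoosterVAE",
    "kl_divergence", "anatomical_penalty", "fovea_crop",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class LatentCode:
    """Posterior summary for one map."""

    d: np.ndarray  # (2,) display latents
    b: np.ndarray  # (8,) booster latents
    d_logvar: np.ndarray
    b_logvar: np.ndarray
    fovea_px: tuple[float, float]  # (x, y) in input-pixel coordinates
    exclude_prob: float

    def __post_init__(self):
        vals = np.concatenate([self.d, self.b, self.d_logvar, self.b_logvar,
                               np.asarray(self.fovea_px, float), [self.exclude_prob]])
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite latent code")
        if not 0.0 <= self.exclude_prob <= 1.0:
            raise ValueError("exclude_prob outside [0, 1]")

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.d, self.b])


@dataclass
class ReconPair:
    """Display / booster / full reconstructions (um, fovea-centered crop raster).

    ``y = y_display + y_booster`` holds elementwise exactly; values are left
    unclipped so the identity is preserved (clip at display time).
    """

    y_display: np.ndarray
    y_booster: np.ndarray
    y: np.ndarray
    x_crop: np.ndarray | None = None


@dataclass
class LossBundle:
    """Loss components (floats, unweighted) plus the differentiable total."""

    recon_display: float
    recon_full: float
    kl_d: float
    kl_b: float
    anat_d1: float
    anat_d2: float
    fovea_loss: float
    exclude_loss: float
    total: float
    total_tensor: Tensor | None = None

    def check_finite(self):
        for f in dataclasses.fields(self):
            if f.name == "total_tensor":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise FloatingPointError(f"non-finite loss term: {f.name}")
        return self


def kl_divergence(mu, logvar):
    """KL(N(mu, exp(logvar)) || N(0, 1)) = sum 0.5 (mu^2 + e^logvar - 1 - logvar).

    Accepts numpy arrays (returns float) or Tensors (returns scalar Tensor).
    """
    if isinstance(mu, Tensor):
        return (mu * mu + nn.exp(logvar) - 1.0 - logvar).sum() * 0.5
    mu = np.asarray(mu, float)
    logvar = np.asarray(logvar, float)
    return float(0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar))


def _kl_per_sample(mu: Tensor, logvar: Tensor) -> Tensor:
    return (mu * mu + nn.exp(logvar) - 1.0 - logvar).sum(axis=1) * 0.5


def anatomical_penalty(d, r_inf, r_sup, anchor: AnchorMap = DEFAULT_ANCHOR):
    """Quadratic pull of (d1, d2) toward the hemifield-ratio anchors.

    Returns ``(anat_d1, anat_d2)`` = ((d1 - t(r_inf))^2, (d2 - t(r_sup))^2);
    zero exactly when the latents sit on their anchors.
    """
    if np.any(np.asarray(r_inf) < 0) or np.any(np.asarray(r_sup) < 0):
        raise ValueError("hemifield ratios must be >= 0")
    d = np.asarray(d, float)
    return float((d[0] - anchor(r_inf)) ** 2), float((d[1] - anchor(r_sup)) ** 2)


def fovea_crop(values: np.ndarray, fovea_px, crop_px: int) -> np.ndarray:
    """Crop a ``crop_px`` square centered on the fovea, edge-replicating
    where the window leaves the image."""
    fy = int(round(fovea_px[1]))
    fx = int(round(fovea_px[0]))
    half = crop_px // 2
    r0, c0 = fy - half, fx - half
    n = values.shape[0]
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bot = max(0, r0 + crop_px - n)
    pad_right = max(0, c0 + crop_px - values.shape[1])
    if any((pad_top, pad_left, pad_bot, pad_right)):
        values = np.pad(values, ((pad_top, pad_bot), (pad_left, pad_right)), mode="edge")
        r0 += pad_top
        c0 += pad_left
    return values[r0 : r0 + crop_px, c0 : c0 + crop_px]


class _Encoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng, dtype):
        super().__init__()
        self.cfg = cfg
        cin = 1
        self.blocks = []
        for c in cfg.channels:
            self.blocks.append(self._mod(nn.ResBlock(cin, c, rng, stride=2, dtype=dtype)))
            cin = c
        s = cfg.image_px
        for _ in cfg.channels:
            s = (s + 1) // 2
        self.flat = cfg.channels[-1] * s * s
        self.trunk = self._mod(nn.Linear(self.flat, cfg.dense_units, rng, dtype=dtype))
        du = cfg.dense_units
        self.head_d = self._mod(nn.Linear(du, 2 * cfg.n_display, rng, dtype=dtype, gain=1.0))
        self.head_b = self._mod(nn.Linear(du, 2 * cfg.n_booster, rng, dtype=dtype, gain=1.0))
        self.head_fovea = self._mod(nn.Linear(du, 2, rng, dtype=dtype, gain=1.0))
        self.head_excl = self._mod(nn.Linear(du, 1, rng, dtype=dtype, gain=1.0))
        # start the posteriors sharp: with log-variances at 0 the sampled
        # latents are unit-variance noise, the decoders learn to ignore them
        # and the mean paths then receive no gradient (posterior collapse);
        # a negative initial log-variance breaks that trap.
        self.head_d.b.data[cfg.n_display :] = -2.0
        self.head_b.b.data[cfg.n_booster :] = -4.0

    def __call__(self, x: Tensor):
        h = x
        for blk in self.blocks:
            h = blk(h)
        h = nn.relu(self.trunk(h.reshape(h.shape[0], -1)))
        nd, nb = self.cfg.n_display, self.cfg.n_booster
        db = self.head_d(h)
        bb = self.head_b(h)
        return {
            "mu_d": _slice_cols(db, 0, nd),
            "logvar_d": _slice_cols(db, nd, 2 * nd),
            "mu_b": _slice_cols(bb, 0, nb),
            "logvar_b": _slice_cols(bb, nb, 2 * nb),
            "fovea": self.head_fovea(h),  # normalized [0, 1] image coordinates
            "excl_logit": self.head_excl(h),
        }


def _slice_cols(t: Tensor, lo: int, hi: int) -> Tensor:
    out = Tensor(t.data[:, lo:hi], (t,))

    def bwd(g):
        full = np.zeros_like(t.data)
        full[:, lo:hi] = g
        nn._acc(t, full)

    out._bwd = bwd
    return out


class _Decoder(nn.Module):
    """Dense expansion followed by upsampling residual blocks."""

    def __init__(self, cfg: ModelConfig, n_latent: int, rng, dtype):
        super().__init__()
        nblocks = len(cfg.channels)
        if cfg.crop_px % (2**nblocks) != 0:
            raise ValueError("crop_px must be divisible by 2**len(channels)")
        self.s0 = cfg.crop_px // (2**nblocks)
        self.c0 = cfg.channels[-1]
        self.fc1 = self._mod(nn.Linear(n_latent, cfg.dense_units, rng, dtype=dtype))
        self.fc2 = self._mod(nn.Linear(cfg.dense_units, self.c0 * self.s0**2, rng, dtype=dtype))
        self.blocks = []
        widths = list(cfg.channels[::-1][1:]) + [cfg.channels[0]]
        cin = self.c0
        for c in widths:
            self.blocks.append(self._mod(nn.UpsampleBlock(cin, c, rng, dtype=dtype)))
            cin = c
        self.out = self._mod(nn.Conv2d(cin, 1, 3, rng, dtype=dtype, gain=1.0))

    def __call__(self, z: Tensor) -> Tensor:
        h = nn.relu(self.fc2(nn.relu(self.fc1(z))))
        h = h.reshape(h.shape[0], self.c0, self.s0, self.s0)
        for blk in self.blocks:
            h = blk(h)
        return self.out(h)


class BoosterVAE(nn.Module):
    """Encoder + display decoder + booster decoder (no shared parameters)."""

    def __init__(self, cfg: ModelConfig = ModelConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        self.encoder = self._mod(_Encoder(cfg, rng, dtype))
        self.display_decoder = self._mod(_Decoder(cfg, cfg.n_display, rng, dtype))
        self.booster_decoder = self._mod(
            _Decoder(cfg, cfg.n_display + cfg.n_booster, rng, dtype)
        )
        self._dtype = dtype
        # validation-calibrated correction subtracted from the raw fovea
        # estimate (input px); set by the trainer, persisted in checkpoints
        self.fovea_bias_px = np.zeros(2)

    # -- normalization ------------------------------------------------------
    def normalize(self, values_um: np.ndarray) -> np.ndarray:
        x = np.clip(values_um / self.cfg.norm_um, 0.0, self.cfg.norm_clip)
        return x.astype(self._dtype)

    def denormalize(self, x: np.ndarray, clip: bool = True) -> np.ndarray:
        out = np.asarray(x, float) * self.cfg.norm_um
        return np.clip(out, 0.0, None) if clip else out

    # -- batched forward ----------------------------------------------------
    def forward(self, x_norm: np.ndarray, rng=None):
        """Run the full model on a normalized batch (N, H, W).

        With ``rng`` the latents are reparameterized samples; without, the
        posterior means are used (temperature 0 — deterministic).
        """
        n = x_norm.shape[0]
        x = Tensor(x_norm.reshape(n, 1, *x_norm.shape[1:]))
        enc = self.encoder(x)
        z_d, z_b = enc["mu_d"], enc["mu_b"]
        if rng is not None:
            eps_d = rng.standard_normal(z_d.shape).astype(self._dtype)
            eps_b = rng.standard_normal(z_b.shape).astype(self._dtype)
            z_d = z_d + nn.exp(enc["logvar_d"] * 0.5) * Tensor(eps_d)
            z_b = z_b + nn.exp(enc["logvar_b"] * 0.5) * Tensor(eps_b)
        y_d = self.display_decoder(z_d)
        y_b = self.booster_decoder(nn.concat([z_d, z_b], axis=1))
        y = y_d + y_b
        out = dict(enc)
        out.update({"x": x, "z_d": z_d, "z_b": z_b, "y_d": y_d, "y_b": y_b, "y": y})
        return out

    def _check_shape(self, values_um: np.ndarray):
        expected = (self.cfg.image_px, self.cfg.image_px)
        if values_um.shape != expected:
            raise ValueError(
                f"expected a {expected[0]} x {expected[1]} map, got {values_um.shape}; "
                "resize upstream — the model never resizes silently"
            )

    # -- public single-map API ----------------------------------------------
    def encode(self, values_um: np.ndarray) -> LatentCode:
        """Posterior means, fovea estimate (input-pixel units), exclusion prob."""
        self._check_shape(values_um)
        out = self.forward(self.normalize(values_um)[None])
        from scipy.special import expit

        fovea = np.clip(
            out["fovea"].data[0] * self.cfg.image_px - self.fovea_bias_px,
            0, self.cfg.image_px - 1,
        )
        return LatentCode(
            d=out["mu_d"].data[0].astype(float),
            b=out["mu_b"].data[0].astype(float),
            d_logvar=out["logvar_d"].data[0].astype(float),
            b_logvar=out["logvar_b"].data[0].astype(float),
            fovea_px=(float(fovea[0]), float(fovea[1])),
            exclude_prob=float(expit(out["excl_logit"].data[0, 0])),
        )

    def encode_batch(self, maps_um: np.ndarray) -> list[LatentCode]:
        from scipy.special import expit

        codes = []
        for lo in range(0, maps_um.shape[0], 64):
            batch = maps_um[lo : lo + 64]
            out = self.forward(self.normalize(batch))
            for i in range(batch.shape[0]):
                fov = np.clip(
                    out["fovea"].data[i] * self.cfg.image_px - self.fovea_bias_px,
                    0, self.cfg.image_px - 1,
                )
                codes.append(
                    LatentCode(
                        d=out["mu_d"].data[i].astype(float),
                        b=out["mu_b"].data[i].astype(float),
                        d_logvar=out["logvar_d"].data[i].astype(float),
                        b_logvar=out["logvar_b"].data[i].astype(float),
                        fovea_px=(float(fov[0]), float(fov[1])),
                        exclude_prob=float(expit(out["excl_logit"].data[i, 0])),
                    )
                )
        return codes

    def decode_display(self, d) -> np.ndarray:
        """Deterministic display reconstruction (um, clipped non-negative)."""
        d = np.asarray(d, dtype=self._dtype).reshape(1, -1)
        y = self.display_decoder(Tensor(d))
        return self.denormalize(y.data[0, 0], clip=True)

    def decode_full(self, code: LatentCode) -> ReconPair:
        """Display + booster reconstruction; y = y_display + y_booster exactly."""
        d = np.asarray(code.d, dtype=self._dtype).reshape(1, -1)
        full = np.asarray(code.full, dtype=self._dtype).reshape(1, -1)
        y_d = self.display_decoder(Tensor(d)).data[0, 0]
        y_b = self.booster_decoder(Tensor(full)).data[0, 0]
        y_d_um = self.denormalize(y_d, clip=False)
        y_b_um = self.denormalize(y_b, clip=False)
        return ReconPair(y_display=y_d_um, y_booster=y_b_um, y=y_d_um + y_b_um)

    def reconstruct(self, values_um: np.ndarray, fovea_px=None) -> ReconPair:
        """Encode-decode one map; attaches the fovea-centered crop of the input."""
        self._check_shape(values_um)
        code = self.encode(values_um)
        pair = self.decode_full(code)
        fov = fovea_px if fovea_px is not None else code.fovea_px
        pair.x_crop = fovea_crop(values_um, fov, self.cfg.crop_px)
        return pair

    # -- training losses ----------------------------------------------------
    def compute_losses(
        self,
        out: dict,
        x_crop_norm: np.ndarray,  # (N, hc, wc) normalized fovea-centered crops
        anchors: np.ndarray,      # (N, 2) anatomical anchor targets t(r_inf), t(r_sup)
        fovea_true_norm: np.ndarray,  # (N, 2) true fovea / image_px
        qc_bad: np.ndarray,       # (N,) bool, poor-quality flags
        weights: dict | None = None,
    ) -> LossBundle:
        """Assemble the weighted training loss.

        Poor-quality samples contribute only the exclusion term; their
        reconstruction, KL, anatomical and fovea terms are masked out.
        """
        cfg = self.cfg
        w = {
            "recon_display": cfg.w_recon_display, "recon_full": cfg.w_recon_full,
            "kl_d": cfg.w_kl_d, "kl_b": cfg.w_kl_b, "anat": cfg.w_anat,
            "fovea": cfg.w_fovea, "exclude": cfg.w_exclude,
        }
        if weights:
            w.update(weights)
        n = x_crop_norm.shape[0]
        good = (~qc_bad).astype(self._dtype)
        n_good = max(float(good.sum()), 1.0)
        gmask = Tensor(good)

        def masked_mean(per_sample: Tensor) -> Tensor:
            return (per_sample * gmask).sum() * (1.0 / n_good)

        target = Tensor(x_crop_norm.reshape(n, 1, *x_crop_norm.shape[1:]).astype(self._dtype))
        npx = float(np.prod(x_crop_norm.shape[1:]))
        rd = masked_mean(((out["y_d"] - target) ** 2).sum(axis=3).sum(axis=2).sum(axis=1) * (1.0 / npx))
        rf = masked_mean(((out["y"] - target) ** 2).sum(axis=3).sum(axis=2).sum(axis=1) * (1.0 / npx))
        kld = masked_mean(_kl_per_sample(out["mu_d"], out["logvar_d"]))
        klb = masked_mean(_kl_per_sample(out["mu_b"], out["logvar_b"]))

        anchors = np.asarray(anchors, dtype=self._dtype)
        anat1 = masked_mean((_slice_cols(out["mu_d"], 0, 1).reshape(n) - Tensor(anchors[:, 0])) ** 2)
        anat2 = masked_mean((_slice_cols(out["mu_d"], 1, 2).reshape(n) - Tensor(anchors[:, 1])) ** 2)

        ftrue = Tensor(np.asarray(fovea_true_norm, dtype=self._dtype))
        fov = masked_mean(((out["fovea"] - ftrue) ** 2).sum(axis=1))

        # binary cross-entropy from logits, label 1 = poor quality, all samples
        z = out["excl_logit"].reshape(n)
        ybad = Tensor(qc_bad.astype(self._dtype))
        excl = (nn.softplus(z) - z * ybad).mean()

        total = (
            w["recon_display"] * rd + w["recon_full"] * rf
            + w["kl_d"] * kld + w["kl_b"] * klb
            + w["anat"] * anat1 + w["anat"] * anat2
            + w["fovea"] * fov + w["exclude"] * excl
        )
        bundle = LossBundle(
            recon_display=rd.item(), recon_full=rf.item(),
            kl_d=kld.item(), kl_b=klb.item(),
            anat_d1=anat1.item(), anat_d2=anat2.item(),
            fovea_loss=fov.item(), exclude_loss=excl.item(),
            total=total.item(), total_tensor=total,
        )
        return bundle.check_finite()


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(path, model: BoosterVAE, extra: dict | None = None) -> None:
    """Weights + config snapshot + seed in one compressed archive."""
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    meta = {
        "config_yaml": config_to_yaml(model.cfg),
        "seed": model.seed,
        "fovea_bias_px": [float(v) for v in model.fovea_bias_px],
        "extra": extra or {},
    }
    np.savez_compressed(path, __meta__=np.asarray(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> BoosterVAE:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg = config_from_yaml(meta["config_yaml"], ModelConfig)
        model = BoosterVAE(cfg, seed=int(meta["seed"]))
        names = sorted(k for k in z.files if k.startswith("param_"))
        model.load_state_arrays([z[k] for k in names])
        model.fovea_bias_px = np.asarray(meta.get("fovea_bias_px", [0.0, 0.0]), float)
    return model
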