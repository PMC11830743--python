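"""Reconstruction and quality-control metrics.

RMSE and SSIM between fovea-centered crops and their reconstructions,
sectoral signed differences over a cohort, fovea-localization error, and
confusion-matrix rates for the poor-quality exclusion flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import SECTORS

# SSIM constants: 11-px Gaussian window (sigma 1.5), K1/K2 from the standard
# formulation, and a fixed dynamic range of 150 um so scores are comparable
# across eyes rather than depending on each image's own range.
SSIM_SIGMA = 1.5
SSIM_TRUNCATE = 3.5  # radius int(3.5 * 1.5 + 0.5) = 5 -> 11-px window
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_RANGE_UM = 150.0


def _check_same_shape(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def image_rmse(a, b) -> float:
    """Root-mean-square pixel difference in um."""
    a, b = _check_same_shape(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def ssim(a, b, data_range: float = SSIM_RANGE_UM) -> float:
    """Mean local structural similarity in [0, 1] (1 = identical).

    Gaussian-weighted local statistics (sigma 1.5, 11-px support), the
    standard stabilizers C1 = (K1 L)^2, C2 = (K2 L)^2, and border cropping
    of half the window radius before averaging.
    """
    a, b = _check_same_shape(a, b)
    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2

    def f(x):
        return gaussian_filter(x, SSIM_SIGMA, truncate=SSIM_TRUNCATE, mode="nearest")

    mu_a, mu_b = f(a), f(b)
    var_a = f(a * a) - mu_a**2
    var_b = f(b * b) - mu_b**2
    cov = f(a * b) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    )
    r = int(SSIM_TRUNCATE * SSIM_SIGMA + 0.5)
    return float(s[r:-r, r:-r].mean())


def sector_signed_diff(x_profiles: dict, recon_profiles: dict):
    """Cohort mean +/- sd of (original - reconstruction) per sector.

    Both arguments map eye key -> SectorProfile; keys must match exactly.
    Returns a dict region -> (mean, sd) including the whole annulus.
    """
    if set(x_profiles) != set(recon_profiles):
        raise ValueError("cohort keys differ between originals and reconstructions")
    keys = sorted(x_profiles)
    out = {}
    regions = ("annulus",) + SECTORS
    for region in regions:
        diffs = []
        for k in keys:
            xo, xr = x_profiles[k], recon_profiles[k]
            if region == "annulus":
                diffs.append(xo.annulus_mean - xr.annulus_mean)
            else:
                diffs.append(xo.sector_means[region] - xr.sector_means[region])
        d = np.asarray(diffs)
        out[region] = (float(d.mean()), float(d.std()))
    return out


def qc_metrics(exclude_probs, qc_bad_labels, threshold: float = 0.5):
    """Accuracy, sensitivity and specificity of the exclusion flag.

    Positive class = poor quality (to be excluded).
    """
    p = np.asarray(exclude_probs, float)
    y = np.asarray(qc_bad_labels).astype(bool)
    pred = p >= threshold
    tp = np.sum(pred & y)
    tn = np.sum(~pred & ~y)
    fp = np.sum(pred & ~y)
    fn = np.sum(~pred & y)
    acc = (tp + tn) / len(y)
    sens = tp / max(tp + fn, 1) if y.any() else float("nan")
    spec = tn / max(tn + fp, 1) if (~y).any() else float("nan")
    return float(acc), float(sens), float(spec)


def fovea_error(estimates, truths):
    """Signed mean +/- sd per axis (estimated - true), in pixels.

    Returns ((mean_x, sd_x), (mean_y, sd_y)).
    """
    est = np.asarray(estimates, float)
    tru = np.asarray(truths, float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must pair up")
    d = est - tru
    return (
        (float(d[:, 0].mean()), float(d[:, 0].std())),
        (float(d[:, 1].mean()), float(d[:, 1].std())),
    )


def paired_improvement_pvalue(errors_full, errors_display) -> float:
    """One-sided Wilcoxon signed-rank p for full < display reconstruction error."""
    from scipy.stats import wilcoxon

    return float(wilcoxon(errors_full, errors_display, alternative="less").pvalue)


@dataclass
class ReconReport:
    """Per-eye reconstruction metrics for the two decoder modes."""

    rows: list

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def summary(self) -> dict:
        import numpy as np

        frame = self.to_frame()
        out = {}
        for mode in ("display", "full"):
            sub = frame[frame["mode"] == mode]
            out[mode] = {
                "rmse_um": (float(sub["rmse_um"].mean()), float(sub["rmse_um"].std())),
                "ssim": (float(sub["ssim"].mean()), float(sub["ssim"].std())),
            }
        return out


def evaluate_reconstructions(model, phantoms) -> ReconReport:
    """Encode-decode each phantom and tabulate RMSE/SSIM against the
    fovea-centered crop (one row per eye per reconstruction mode)."""
    from .model import fovea_crop

    rows = []
    codes = model.encode_batch(np.stack([p.values_um for p in phantoms]))
    for i, (p, code) in enumerate(zip(phantoms, codes)):
        pair = model.decode_full(code)
        xc = fovea_crop(p.values_um, p.fovea_px, model.cfg.crop_px)
        for mode, y in (("display", pair.y_display), ("full", pair.y)):
            rows.append(
                {
                    "eye": i,
                    "mode": mode,
                    "rmse_um": image_rmse(xc, y),
                    "ssim": ssim(xc, y),
                }
            )
    return ReconReport(rows=rows)
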