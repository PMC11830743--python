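"""Geometry and statistics of the elliptical annulus sector grid."""

import numpy as np
import pytest

from gclspace import annulus
from gclspace.annulus import hemifield_ratios, sector_masks, sector_means
from gclspace.config import DEFAULT_ANNULUS, DEFAULT_GRID, SECTORS
from gclspace.phantom import PhantomParams, make_gcipl_map, normal_template


def test_masks_partition_annulus():
    """Six sector masks are pairwise disjoint and tile the annulus exactly."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        fovea = tuple(rng.uniform(85, 115, size=2))
        masks = sector_masks(fovea)
        union = np.zeros_like(masks.annulus)
        total = 0
        for m in masks.sectors.values():
            assert not np.any(union & m), "sector masks overlap"
            union |= m
            total += int(m.sum())
        assert np.array_equal(union, masks.annulus)
        assert total == int(masks.annulus.sum())


def test_superior_inferior_mirror_symmetry():
    """With the fovea on the pixel-center symmetry axis, S and I masks are
    mirror images across the horizontal meridian."""
    fovea = DEFAULT_GRID.center_px  # (99.5, 99.5): rows mirror exactly
    masks = sector_masks(fovea)
    s, i = masks.sectors["S"], masks.sectors["I"]
    assert np.array_equal(s[::-1, :], i)
    for a, b in (("SN", "IN"), ("ST", "IT")):
        assert masks.sectors[a].sum() == masks.sectors[b].sum()


def test_annulus_pixel_count_matches_ellipse_area():
    """Pixel count agrees with pi*(h_o*v_o - h_i*v_i)/pitch^2 within 1%."""
    g = DEFAULT_ANNULUS
    expected = np.pi * (g.h_outer * g.v_outer - g.h_inner * g.v_inner) / DEFAULT_GRID.pitch_mm**2
    masks = sector_masks(DEFAULT_GRID.center_px)
    assert masks.annulus.sum() == pytest.approx(expected, rel=0.01)


def test_constant_map_sector_means_exact():
    m = np.full((200, 200), 70.0)
    prof = sector_means(m, DEFAULT_GRID.center_px)
    assert prof.annulus_mean == 70.0
    for s in SECTORS:
        assert prof.sector_means[s] == 70.0
    # weighted-consistency invariant
    w = np.array([prof.pixel_counts[s] for s in SECTORS], float)
    means = np.array([prof.sector_means[s] for s in SECTORS])
    assert prof.annulus_mean == pytest.approx(np.sum(w * means) / w.sum(), abs=1e-12)


def test_symmetric_phantom_equal_sector_means():
    """The noise-free normal phantom has all six sector means equal to 0.1 um."""
    tmap = normal_template()
    prof = sector_means(tmap.values_um, tmap.fovea_px)
    means = [prof.sector_means[s] for s in SECTORS]
    assert max(means) - min(means) < 0.1


def _pixel_loop_profile(values, fovea, pitch):
    """Independent brute-force oracle: per-pixel membership and running sums."""
    g = DEFAULT_ANNULUS
    order = ("ST", "S", "SN", "IN", "I", "IT")
    sums = {s: 0.0 for s in order}
    counts = {s: 0 for s in order}
    fx, fy = fovea
    ny, nx = values.shape
    for r in range(ny):
        for c in range(nx):
            dx = (c - fx) * pitch
            dy = (r - fy) * pitch
            if (dx / g.h_inner) ** 2 + (dy / g.v_inner) ** 2 < 1.0:
                continue
            if (dx / g.h_outer) ** 2 + (dy / g.v_outer) ** 2 > 1.0:
                continue
            theta = np.degrees(np.arctan2(-dy / g.v_outer, -dx / g.h_outer)) % 360.0
            sec = order[min(int(theta // 60.0), 5)]
            sums[sec] += values[r, c]
            counts[sec] += 1
    return {s: sums[s] / counts[s] for s in order}, counts


def test_sector_means_match_pixel_loop_oracle():
    """Vectorized sector means agree with a naive pixel loop to 1e-9."""
    p = PhantomParams(pattern_class="inferior", severity=0.5, noise_sd_um=0.0)
    tmap = make_gcipl_map(p, seed=3)
    prof = sector_means(tmap.values_um, tmap.fovea_px)
    loop_means, loop_counts = _pixel_loop_profile(
        tmap.values_um, tmap.fovea_px, DEFAULT_GRID.pitch_mm
    )
    for s in SECTORS:
        assert prof.pixel_counts[s] == loop_counts[s]
        assert prof.sector_means[s] == pytest.approx(loop_means[s], abs=1e-9)
    inf = np.mean([loop_means[s] for s in ("IT", "I", "IN")])
    sup = np.mean([loop_means[s] for s in ("ST", "S", "SN")])
    assert inf < sup  # inferior phantom thins the inferior hemifield


def test_profile_linear_in_map():
    """profile(a*A + b*B) = a*profile(A) + b*profile(B)."""
    rng = np.random.default_rng(0)
    a_map = rng.uniform(40, 100, (200, 200))
    b_map = rng.uniform(40, 100, (200, 200))
    fov = (103.0, 97.0)
    pa = sector_means(a_map, fov)
    pb = sector_means(b_map, fov)
    pc = sector_means(0.3 * a_map + 1.7 * b_map, fov)
    for s in SECTORS:
        assert pc.sector_means[s] == pytest.approx(
            0.3 * pa.sector_means[s] + 1.7 * pb.sector_means[s], abs=1e-9
        )


def test_hemifield_ratios():
    const = np.full((200, 200), 80.0)
    prof = sector_means(const, DEFAULT_GRID.center_px)
    assert hemifield_ratios(prof, 80.0) == pytest.approx((1.0, 1.0))
    half = sector_means(const * 0.5, DEFAULT_GRID.center_px)
    assert hemifield_ratios(half, 80.0) == pytest.approx((0.5, 0.5))
    with pytest.raises(ValueError):
        hemifield_ratios(prof, 0.0)


def test_inferior_ratio_falls_with_severity_superior_stable():
    r_prev = None
    for s in (0.0, 0.3, 0.6, 0.9):
        tmap = make_gcipl_map(
            PhantomParams(pattern_class="inferior", severity=s, noise_sd_um=0.0), 0
        )
        prof = sector_means(tmap.values_um, tmap.fovea_px)
        r_inf, r_sup = hemifield_ratios(prof, 80.0)
        if r_prev is not None:
            assert r_inf < r_prev[0]
            assert abs(r_sup - r_prev[1]) / r_prev[1] < 0.02
        r_prev = (r_inf, r_sup)


def test_clipped_fovea_warns_and_flags():
    with pytest.warns(UserWarning):
        prof = sector_means(np.full((200, 200), 70.0), (20.0, 100.0))
    assert prof.clipped


def test_os_laterality_swaps_nasal_temporal():
    """Mirroring the map and passing OS yields identical anatomical sectors."""
    rng = np.random.default_rng(5)
    values = rng.uniform(40, 100, (200, 200))
    fov = (90.0, 99.5)
    od = sector_means(values, fov)
    mirrored = values[:, ::-1]
    os_ = sector_means(mirrored, (199 - fov[0], fov[1]), laterality="OS")
    for s in SECTORS:
        assert os_.sector_means[s] == pytest.approx(od.sector_means[s], abs=1e-9)


def test_fovea_outside_image_rejected():
    with pytest.raises(ValueError):
        sector_masks((250.0, 100.0))
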