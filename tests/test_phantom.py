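"""Synthetic GCIPL phantom generator: rendering, series, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gclspace import annulus
from gclspace.config import DEFAULT_CALIBRATION, SECTORS
from gclspace.phantom import (
    ClassSpec,
    PhantomParams,
    calibration_cohort_spec,
    make_cohort,
    make_eye_series,
    make_gcipl_map,
    normal_template,
)


def test_severity_zero_equals_template():
    """A severity-0, noise-free map is exactly the normal template, and the
    six sector means coincide by up/down symmetry."""
    p = PhantomParams(pattern_class="normal", severity=0.0, noise_sd_um=0.0)
    tmap = make_gcipl_map(p, seed=99)
    template = normal_template()
    assert np.array_equal(tmap.values_um, template.values_um)
    prof = annulus.sector_means(tmap.values_um, tmap.fovea_px)
    sup = [prof.sector_means[s] for s in ("SN", "S", "ST")]
    inf = [prof.sector_means[s] for s in ("IN", "I", "IT")]
    np.testing.assert_allclose(sorted(sup), sorted(inf), atol=1e-12)


def test_determinism_bit_identical():
    p = PhantomParams(pattern_class="inferior", severity=0.4)
    a = make_gcipl_map(p, seed=123)
    b = make_gcipl_map(p, seed=123)
    assert np.array_equal(a.values_um, b.values_um)
    c = make_gcipl_map(p, seed=124)
    assert not np.array_equal(a.values_um, c.values_um)


def test_inferior_deficit_linear_in_severity():
    """Above-floor integral over the inferior hemifield scales linearly in
    severity, checked against brute-force pixel sums of rendered maps."""
    floor = DEFAULT_CALIBRATION.base_floor_um

    def hemi_sum(severity):
        p = PhantomParams(pattern_class="inferior", severity=severity, noise_sd_um=0.0)
        tmap = make_gcipl_map(p, 0)
        fy = int(round(tmap.fovea_px[1]))
        return float(np.sum(tmap.values_um[fy + 1 :, :] - floor))

    s0, s_half, s1 = hemi_sum(0.0), hemi_sum(0.5), hemi_sum(1.0)
    assert s_half == pytest.approx(0.5 * (s0 + s1), rel=1e-9)
    # the severity-1 bump removes the full bump mass; deficit at 0.5 is half
    assert (s0 - s_half) == pytest.approx(0.5 * (s0 - s1), rel=1e-9)
    assert s1 < s_half < s0


@settings(max_examples=20, deadline=None)
@given(
    s1=st.floats(0.0, 1.0), s2=st.floats(0.0, 1.0),
    pattern=st.sampled_from(["inferior", "superior", "diffuse"]),
)
def test_affected_hemifield_monotone_in_severity(s1, s2, pattern):
    lo, hi = sorted((s1, s2))
    vals = []
    for s in (lo, hi):
        p = PhantomParams(pattern_class=pattern, severity=s, noise_sd_um=0.0)
        tmap = make_gcipl_map(p, 11)
        prof = annulus.sector_means(tmap.values_um, tmap.fovea_px)
        sectors = ("IT", "I", "IN") if pattern == "inferior" else ("ST", "S", "SN")
        vals.append(np.mean([prof.sector_means[s_] for s_ in sectors]))
    assert vals[1] <= vals[0] + 1e-12


def test_poor_quality_artifact_drops_pixels():
    p = PhantomParams(artifact="poor_quality")
    tmap = make_gcipl_map(p, seed=5)
    assert not tmap.qc_good
    assert np.mean(tmap.values_um == 0.0) >= 0.15


def test_erm_artifact_adds_superior_temporal_thickening():
    base = make_gcipl_map(PhantomParams(noise_sd_um=0.0), 7)
    erm = make_gcipl_map(
        PhantomParams(noise_sd_um=0.0, artifact="erm_focal_thickening"), 7
    )
    diff = erm.values_um - base.values_um
    assert diff.min() >= -1e-9
    assert diff.max() > 20.0
    r, c = np.unravel_index(np.argmax(diff), diff.shape)
    assert r < 100 and c < 100  # superior-temporal quadrant in OD orientation


def test_os_map_is_mirrored():
    p_od = PhantomParams(pattern_class="inferior", severity=0.5, noise_sd_um=0.0)
    p_os = PhantomParams(pattern_class="inferior", severity=0.5, noise_sd_um=0.0,
                         laterality="OS")
    od = make_gcipl_map(p_od, 1)
    os_ = make_gcipl_map(p_os, 1)
    assert np.array_equal(os_.values_um, od.values_um[:, ::-1])
    back = os_.to_od_orientation()
    assert np.array_equal(back.values_um, od.values_um)
    assert back.fovea_px == od.fovea_px


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        PhantomParams(severity=1.5)
    with pytest.raises(ValueError):
        PhantomParams(ring_radius_mm=3.5)
    with pytest.raises(ValueError):
        PhantomParams(noise_sd_um=-1.0)
    with pytest.raises(ValueError):
        PhantomParams(base_floor_um=float("nan"))
    with pytest.raises(ValueError):
        PhantomParams(pattern_class="nasal")


def test_series_severity_schedule_and_label():
    """severity_k = min(1, s0 + k*rate); beyond_normal_range iff the final
    severity exceeds the 0.2 normal-band threshold."""
    p = PhantomParams(pattern_class="inferior", severity=0.1)
    series = make_eye_series(p, n_visits=4, progression_rate=0.15, seed=2)
    assert series.severities == pytest.approx([0.1, 0.25, 0.40, 0.55])
    assert series.progression_label == "beyond_normal_range"
    assert len(series.intervals_days) == 3

    flat = make_eye_series(PhantomParams(), n_visits=3, progression_rate=0.0, seed=2)
    assert flat.progression_label == "within_normal_range"
    assert flat.severities == [0.0, 0.0, 0.0]


def test_naion_edema_baseline_thickening():
    """With the edema flag, visit 0 is thicker than the normal template mean
    while a progressed later visit is thinner."""
    template = normal_template()
    t_prof = annulus.sector_means(template.values_um, template.fovea_px)
    p = PhantomParams(pattern_class="superior", severity=0.1, noise_sd_um=0.0)
    series = make_eye_series(p, n_visits=4, progression_rate=0.25, seed=3,
                             edema_baseline=True, disease_label="NAION")
    def annmean(k):
        m = series.maps[k]
        return annulus.sector_means(m.values_um, m.fovea_px).annulus_mean
    assert annmean(0) > t_prof.annulus_mean
    assert annmean(3) < t_prof.annulus_mean


def test_empty_cohort():
    spec = {"normal": ClassSpec(n_eyes=0, patterns={"normal": 1.0})}
    series, manifest = make_cohort(spec, seed=0)
    assert series == []
    assert len(manifest) == 0
    assert list(manifest.columns)[:3] == ["subject_id", "eye", "visit_idx"]


def test_cohort_manifest_deterministic(tmp_path):
    spec = calibration_cohort_spec(4)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    make_cohort(spec, seed=42, out_dir=d1)
    make_cohort(spec, seed=42, out_dir=d2)
    assert (d1 / "manifest.csv").read_bytes() == (d2 / "manifest.csv").read_bytes()


def test_cohort_pattern_assignment():
    series, manifest = make_cohort(calibration_cohort_spec(30), seed=1)
    by_disease = {}
    for s in series:
        by_disease.setdefault(s.disease_label, []).append(s.pattern_class)
    assert set(by_disease["ON"]) == {"diffuse"}
    assert set(by_disease["NAION"]) == {"superior"}
    assert set(by_disease["normal"]) == {"normal"}
    glau = by_disease["glaucoma"]
    assert glau.count("inferior") > glau.count("superior") > 0
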