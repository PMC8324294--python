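"""Tests of SFM flattening, segmentation, morphometry and classification."""

import numpy as np
import pytest

from repairscope._geometry import convex_hull_area, mask_solidity
from repairscope.sfm import (
    HeightImage,
    MonomerReference,
    analyze_height_image,
    calibrate_monomer_volume,
    classify_oligomer,
    classify_shape,
    flatten_background,
    particle_metrics,
    population_summary,
    records_to_frame,
    segment_particles,
)
from repairscope.simulate import SFMSimParams, simulate_sfm_image

from conftest import clean_sfm_params


def brute_force_hull_area(mask):
    """Oracle: hull area of pixel-corner points by testing all point pairs.

    A directed pair i->j is a hull edge iff every point lies on or to one
    side of the line through it and every collinear point projects inside
    the segment (so only maximal edges count); the area follows from the
    shoelace sum over the accepted directed edges.
    """
    rows, cols = np.nonzero(mask)
    corners = set()
    for r, c in zip(rows, cols):
        for dr in (-0.5, 0.5):
            for dc in (-0.5, 0.5):
                corners.add((r + dr, c + dc))
    pts = np.array(sorted(corners))
    n = len(pts)
    area2 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = pts[i], pts[j]
            d = b - a
            rel = pts - a
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if np.any(cross > 1e-9):
                continue
            t = rel[np.abs(cross) <= 1e-9] @ d / (d @ d)
            if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
                continue
            area2 += a[0] * b[1] - b[0] * a[1]
    return abs(area2) / 2.0


# ----------------------------------------------------------------- geometry


def test_plus_shape_solidity_five_sevenths():
    """A plus of five unit squares has hull area 7, hence solidity 5/7."""
    mask = np.zeros((5, 5), bool)
    mask[2, 1:4] = True
    mask[1:4, 2] = True
    assert convex_hull_area(mask) == pytest.approx(7.0)
    assert mask_solidity(mask) == pytest.approx(5.0 / 7.0)
    assert brute_force_hull_area(mask) == pytest.approx(7.0)


def test_rectangle_solidity_one():
    mask = np.zeros((10, 12), bool)
    mask[2:8, 3:11] = True
    assert mask_solidity(mask) == pytest.approx(1.0)


def test_hull_area_matches_brute_force_oracle():
    """scipy-based hull equals the all-pairs oracle on random small masks."""
    rng = np.random.default_rng(31)
    for _ in range(8):
        mask = np.zeros((14, 14), bool)
        n = rng.integers(5, 40)
        rr = rng.integers(2, 12, n)
        cc = rng.integers(2, 12, n)
        mask[rr, cc] = True
        assert mask.sum() <= 200
        assert convex_hull_area(mask) == pytest.approx(brute_force_hull_area(mask), rel=1e-9)


def test_convex_disc_solidity_high_and_converging():
    """Digitized discs score high solidity, increasing toward 1 with size.

    The corner-hull covers the staircase notches of a digitized circle,
    so the ratio is 1 - O(1/R): ~0.93 at 24 px diameter, above 0.95 by
    60 px.  Axis-aligned rectangles are exactly 1 (see above).
    """
    sols = []
    for R in (12, 20, 30):
        n = 2 * R + 8
        yy, xx = np.mgrid[0:n, 0:n]
        disc = (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= R**2
        sols.append(mask_solidity(disc))
    assert sols[0] >= 0.89
    assert sols[0] < sols[1] < sols[2]
    assert sols[2] >= 0.95


# --------------------------------------------------------------- flattening


def test_flatten_tilt_only_residual_below_noise():
    p = clean_sfm_params(n_particles=0, plane_tilt=3.0, height_noise_sigma=0.05, seed=41)
    img, _ = simulate_sfm_image(p)
    flat = flatten_background(img)
    assert flat.data.std() <= p.height_noise_sigma * 1.05
    assert abs(np.median(flat.data)) < 0.01


def test_flatten_idempotent_on_flat_image():
    p = clean_sfm_params(n_particles=5, seed=42)
    img, _ = simulate_sfm_image(p)
    flat = flatten_background(img)
    assert np.allclose(flat.data, img.data, atol=1e-6)


def test_flatten_preserves_particle_volume():
    """Tilt + artifacts removed: measured volume within 2% of assigned."""
    p = SFMSimParams(n_particles=1, class_mixture=(0, 0, 0, 1), shape_mixture=(1, 0, 0),
                     plane_tilt=3.0, line_offset_sigma=0.1, height_noise_sigma=0.05,
                     tip_sigma=0.0, seed=43)
    img, gt = simulate_sfm_image(p)
    flat = flatten_background(img)
    masks = segment_particles(flat, height_threshold=0.3)
    assert len(masks) == 1
    rec = particle_metrics(masks[0], flat)
    assert rec.volume == pytest.approx(gt.volume_nm3.iloc[0], rel=0.02)


# ------------------------------------------------------------- segmentation


def test_two_discs_two_masks():
    data = np.zeros((64, 64))
    yy, xx = np.mgrid[0:64, 0:64]
    data[(yy - 20) ** 2 + (xx - 20) ** 2 <= 25] = 2.0
    data[(yy - 45) ** 2 + (xx - 45) ** 2 <= 25] = 2.0
    masks = segment_particles(HeightImage(data=data), height_threshold=0.5, min_area=10)
    assert len(masks) == 2


def test_border_touching_disc_discarded():
    data = np.zeros((64, 64))
    yy, xx = np.mgrid[0:64, 0:64]
    data[(yy - 0) ** 2 + (xx - 30) ** 2 <= 49] = 2.0
    assert segment_particles(HeightImage(data=data)) == []


def test_segmentation_counts_match_ground_truth():
    p = SFMSimParams(n_particles=25, seed=44)
    img, gt = simulate_sfm_image(p)
    masks = segment_particles(flatten_background(img))
    assert len(masks) == len(gt)


# -------------------------------------------------------------- morphometry


def test_cylinder_volume_exact():
    data = np.zeros((32, 32))
    data[10:20, 10:20] = 2.5  # flat-topped, footprint 100 px
    img = HeightImage(data=data, pixel_size=2.0)
    mask = data > 0
    rec = particle_metrics(mask, img)
    assert rec.volume == pytest.approx(2.5 * 100 * 4.0)
    assert rec.area == pytest.approx(100 * 4.0)
    assert rec.solidity == pytest.approx(1.0)


def test_volume_scales_linearly_with_height():
    p = clean_sfm_params(n_particles=3, seed=45)
    img, _ = simulate_sfm_image(p)
    base = [particle_metrics(m, img).volume for m in segment_particles(img, 0.1)]
    for k in (0.5, 2.0):
        scaled = HeightImage(data=img.data * k, pixel_size=img.pixel_size)
        vols = [particle_metrics(m, scaled).volume for m in segment_particles(scaled, 0.1 * k)]
        assert vols == pytest.approx([k * v for v in base], rel=1e-9)


def test_tiny_mask_raises():
    img = HeightImage(data=np.ones((8, 8)))
    mask = np.zeros((8, 8), bool)
    mask[2, 2:4] = True
    with pytest.raises(ValueError):
        particle_metrics(mask, img)


def test_volume_conserved_through_tip_broadening():
    """Noise-free image: total measured volume within 2% of assigned."""
    p = SFMSimParams(n_particles=20, tip_sigma=3.0, plane_tilt=0.0,
                     line_offset_sigma=0.0, height_noise_sigma=0.0, seed=46)
    img, gt = simulate_sfm_image(p)
    # field integral conserved through Gaussian broadening (<1%)
    total = img.data.sum() * img.pixel_size**2
    assert total == pytest.approx(gt.volume_nm3.sum(), rel=0.01)
    vols = [particle_metrics(m, img).volume for m in segment_particles(img, height_threshold=0.02, min_area=10)]
    assert len(vols) == len(gt)
    assert sum(vols) == pytest.approx(gt.volume_nm3.sum(), rel=0.02)


# ------------------------------------------------------------ classification


@pytest.mark.parametrize("ratio, expected", [(3.0, "rod"), (1.0, "globular"), (1.5, "globular"), (1.51, "rod")])
def test_classify_shape_threshold(ratio, expected):
    from repairscope.sfm import ParticleRecord

    rec = ParticleRecord(0, np.zeros((1, 2)), (0, 0), 1.0, 1.0, 1.0, axis_ratio=ratio)
    assert classify_shape(rec) == expected


def test_rod_template_measures_as_rod():
    p = clean_sfm_params(n_particles=10, shape_mixture=(0, 1, 0), class_mixture=(0, 0, 0, 1), seed=47)
    img, _ = simulate_sfm_image(p)
    recs = [particle_metrics(m, img) for m in segment_particles(img, 0.1)]
    assert all(r.axis_ratio > 1.5 for r in recs)


@pytest.mark.parametrize(
    "volume, expected",
    [(56.0, "excluded"), (99.0, "excluded"), (418.0 * 0.4, "excluded"), (418.0, "monomer"),
     (418.0 * 2.0, "dimer"), (418.0 * 4.0, "3-4mer"), (418.0 * 7.0, ">tetramer"),
     (418.0 * 6.0, ">tetramer"), (418.0 * 1.5, "dimer")],
)
def test_classify_oligomer_bins(volume, expected):
    assert classify_oligomer(volume, MonomerReference()) == expected


def test_monomer_reference_validation():
    with pytest.raises(ValueError):
        MonomerReference(v1=50.0, exclusion_threshold=100.0)


def test_calibrate_monomer_volume_on_mixture():
    rng = np.random.default_rng(48)
    vols = np.concatenate([rng.normal(400, 40, 300), rng.normal(800, 80, 80), rng.normal(2800, 200, 40)])
    v1 = calibrate_monomer_volume(vols)
    assert v1 == pytest.approx(400, rel=0.1)


# ------------------------------------------------------- population summary


def test_population_summary_fractions():
    p = clean_sfm_params(n_particles=10, class_mixture=(0.3, 0, 0, 0.7), seed=49)
    img, gt = simulate_sfm_image(p)
    recs = analyze_height_image(img, MonomerReference(), height_threshold=0.1, flatten=False)
    summary = population_summary(recs)
    frac = summary["class_fractions"].set_index("oligomer_class")["fraction"]
    counts = gt.oligomer_class.value_counts()
    for cls in ("monomer", ">tetramer"):
        assert frac[cls] == pytest.approx(counts.get(cls, 0) / len(gt))
    assert summary["class_fractions"]["fraction"].sum() == pytest.approx(1.0)


def test_population_summary_all_convex_solidity():
    p = clean_sfm_params(n_particles=8, shape_mixture=(1, 0, 0), class_mixture=(0, 0, 0, 1), seed=50)
    img, _ = simulate_sfm_image(p)
    recs = analyze_height_image(img, MonomerReference(), height_threshold=0.1, flatten=False)
    hist = population_summary(recs)["solidity_histogram"]
    # compact particles pixelate to ~0.9; all mass sits in the top bins
    mass_high = hist[hist.bin_left >= 0.85 - 1e-9]["count"].sum()
    assert mass_high == hist["count"].sum()


def test_population_summary_all_excluded_raises():
    from repairscope.sfm import ParticleRecord

    recs = [ParticleRecord(0, np.zeros((3, 2)), (0, 0), 1.0, 56.0, 1.0, 1.0, oligomer_class="excluded")]
    with pytest.raises(ValueError):
        population_summary(recs)


def test_mixture_recovered_within_multinomial_error():
    """Generated class probabilities are recovered by the full pipeline."""
    mix = (0.1, 0.2, 0.2, 0.5)
    ref = MonomerReference()
    counts = {c: 0 for c in ("monomer", "dimer", "3-4mer", ">tetramer")}
    total = 0
    for s in range(4):
        p = SFMSimParams(n_particles=40, class_mixture=mix, seed=60 + s)
        img, _ = simulate_sfm_image(p)
        for r in analyze_height_image(img, ref):
            if r.oligomer_class in counts:
                counts[r.oligomer_class] += 1
                total += 1
    for frac, cls in zip(mix, counts):
        sd = np.sqrt(frac * (1 - frac) / total)
        assert abs(counts[cls] / total - frac) < 3 * sd + 0.02


def test_free_rad51_all_below_monomer_bin():
    """Pure contaminant fields carry only sub-half-monomer volumes."""
    p = clean_sfm_params(n_particles=8, free_rad51_fraction=1.0, seed=51)
    img, gt = simulate_sfm_image(p)
    assert (gt.volume_nm3 < 0.5 * p.monomer_volume).all()
    recs = analyze_height_image(img, MonomerReference(), height_threshold=0.1, flatten=False)
    assert all(r.oligomer_class == "excluded" for r in recs)


def test_simulate_reproducible_and_overlap_error():
    p = SFMSimParams(n_particles=10, seed=52)
    img_a, gt_a = simulate_sfm_image(p)
    img_b, gt_b = simulate_sfm_image(SFMSimParams(n_particles=10, seed=52))
    assert np.array_equal(img_a.data, img_b.data)
    assert gt_a.equals(gt_b)
    with pytest.raises(ValueError):
        simulate_sfm_image(SFMSimParams(image_size=64, n_particles=100, seed=53))


def test_records_to_frame_columns():
    p = clean_sfm_params(n_particles=3, seed=54)
    img, _ = simulate_sfm_image(p)
    recs = analyze_height_image(img, MonomerReference(), height_threshold=0.1, flatten=False)
    df = records_to_frame(recs)
    assert {"particle_id", "volume_nm3", "solidity", "axis_ratio", "oligomer_class"} <= set(df.columns)
    assert len(df) == 3
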