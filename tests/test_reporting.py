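import math

import numpy as np
import pytest

from cracksep.circular_stats import AngleSample, AxialSummary, rao_spacing_test
from cracksep.group_stats import SeriesAreas, compare_all_pairs
from cracksep.image_io import IntensityImage
from cracksep.reporting import (
    ImageOrientationSummary,
    invert_intensities,
    read_crack_csv,
    render_comparison,
    render_image_overlays,
    render_polar_histogram,
    vector_cross_segments,
    write_crack_csv,
    write_series_summary,
)
from cracksep.segmentation import CrackRegion, SegmentationParams, segment_image
from cracksep.shape_analysis import CrackDescriptor, describe_crack


def make_descriptor(label=1, lam1=9.0, lam2=1.0):
    return CrackDescriptor(
        label=label, centroid=(10.0, 12.0), area_px=30, area_um2=7.5,
        angle_deg=42.123456, anisotropy=(lam1 - lam2) / (lam1 + lam2),
        eigenvalues=(lam1, lam2),
        eigenvectors=((1.0, 0.0), (0.0, 1.0)),
    )


def test_csv_has_header_plus_one_row_per_crack(tmp_path):
    path = write_crack_csv([make_descriptor(i) for i in range(1, 4)], tmp_path / "c.csv")
    lines = path.read_text().splitlines()
    assert len(lines) == 4
    assert lines[0].startswith("label,centroid_x,centroid_y,area_px,area_um2,angle_deg")


def test_empty_descriptor_list_writes_header_only(tmp_path):
    path = write_crack_csv([], tmp_path / "c.csv")
    assert len(path.read_text().splitlines()) == 1


def test_csv_round_trip_to_six_significant_digits(tmp_path, simple_image):
    image, _ = simple_image
    regions = segment_image(image, SegmentationParams(threshold=110, min_area_px=5,
                                                      max_area_px=5000))
    descriptors = [describe_crack(r, 0.4) for r in regions]
    path = write_crack_csv(descriptors, tmp_path / "c.csv")
    for orig, back in zip(descriptors, read_crack_csv(path)):
        assert back.label == orig.label
        assert back.area_px == orig.area_px
        assert back.angle_deg == pytest.approx(orig.angle_deg, rel=1e-5)
        assert back.anisotropy == pytest.approx(orig.anisotropy, rel=1e-5)
        assert back.eigenvalues[0] == pytest.approx(orig.eigenvalues[0], rel=1e-5)
        assert back.centroid[0] == pytest.approx(orig.centroid[0], rel=1e-5)


def test_intensity_inversion_identity():
    pixels = np.full((5, 5), 100, dtype=np.uint8)
    assert np.all(invert_intensities(pixels) == 155)


def test_vector_cross_half_length_is_twice_root_eigenvalue():
    d = make_descriptor(lam1=9.0, lam2=4.0)
    segments = vector_cross_segments(d)
    (p0, p1), (q0, q1) = segments
    half_major = math.dist(p0, p1) / 2.0
    half_minor = math.dist(q0, q1) / 2.0
    assert half_major == pytest.approx(2.0 * math.sqrt(9.0))  # 6 px
    assert half_minor == pytest.approx(2.0 * math.sqrt(4.0))
    # segments are orthogonal and pass through the centroid
    mid = ((p0[0] + p1[0]) / 2.0, (p0[1] + p1[1]) / 2.0)
    assert mid == pytest.approx(d.centroid)


def test_overlay_rendering_writes_three_figures(tmp_path, simple_image):
    image, _ = simple_image
    regions = segment_image(image, SegmentationParams(threshold=110, min_area_px=5,
                                                      max_area_px=5000))
    descriptors = [describe_crack(r, 1.0) for r in regions]
    paths = render_image_overlays(image, descriptors, regions, tmp_path / "img")
    assert [p.name for p in paths] == ["img_inverted.pdf", "img_labels.pdf",
                                       "img_vectors.pdf"]
    assert all(p.stat().st_size > 0 for p in paths)


def test_overlays_valid_with_zero_cracks(tmp_path):
    image = IntensityImage(pixels=np.full((32, 32), 50, dtype=np.uint8))
    paths = render_image_overlays(image, [], [], tmp_path / "empty")
    assert len(paths) == 3 and all(p.exists() for p in paths)
    hist = render_polar_histogram(None, tmp_path / "empty_polarhist.pdf")
    assert hist.exists()


def test_series_summary_structure_and_na_handling(tmp_path):
    aligned = ImageOrientationSummary(
        "img0", AxialSummary(mean_angle_deg=37.0, resultant_length=1.0, n=6), 0.8
    )
    undefined = ImageOrientationSummary(
        "img1", AxialSummary(mean_angle_deg=math.nan, resultant_length=0.0, n=3), 0.2
    )
    pooled = ImageOrientationSummary(
        "pooled", AxialSummary(mean_angle_deg=37.0, resultant_length=1.0, n=9), 0.6
    )
    rao = rao_spacing_test(AngleSample(np.full(9, 37.0)))
    path = write_series_summary([aligned, undefined], pooled, rao, tmp_path / "s.txt")
    text = path.read_text()
    lines = text.splitlines()
    assert lines[0].startswith("image\t")
    assert lines[1].startswith("img0\t37\t1\t")
    assert "img1\tNA\t" in text
    assert "pooled_resultant_length\t1" in text
    assert "rao_spacing_U_deg" in text and "significant_angular_bias" in text
    assert "NA mean angle" in text


def test_comparison_outputs_and_block_counts(tmp_path, rng):
    trio = [
        SeriesAreas("s1", rng.normal(50, 5, 10)),
        SeriesAreas("s2", rng.normal(60, 5, 10)),
        SeriesAreas("s3", rng.normal(55, 5, 10)),
    ]
    results = compare_all_pairs(trio)
    pdf, txt = render_comparison(results, trio, tmp_path / "comparison")
    assert pdf.exists() and txt.exists()
    text = txt.read_text()
    assert text.count("comparison\t") == 3  # C(3,2) pairwise blocks
    assert "correction" in text  # multiple-comparison caveat announced
    # routing line re-parsed agrees with the recorded p-values
    for block in text.split("comparison\t")[1:]:
        shapiro_line = [l for l in block.splitlines() if l.startswith("shapiro_p")][0]
        chosen = [l for l in block.splitlines() if l.startswith("chosen_test")][0].split("\t")[1]
        p1, p2 = map(float, shapiro_line.split("\t")[1:])
        if min(p1, p2) < 0.05:
            assert chosen == "wilcoxon_rank_sum"
        else:
            assert chosen in ("student_t", "welch_t")


def test_rerunning_reports_is_byte_identical(tmp_path, simple_image):
    image, _ = simple_image
    regions = segment_image(image, SegmentationParams(threshold=110, min_area_px=5,
                                                      max_area_px=5000))
    descriptors = [describe_crack(r, 1.0) for r in regions]
    p1 = write_crack_csv(descriptors, tmp_path / "a.csv")
    p2 = write_crack_csv(descriptors, tmp_path / "b.csv")
    assert p1.read_bytes() == p2.read_bytes()
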