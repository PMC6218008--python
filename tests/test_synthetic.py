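import numpy as np
import pytest

from helpers import ellipse_pixels

from cracksep.errors import NamingConventionError, SceneError
from cracksep.image_io import scan_dataset
from cracksep.segmentation import SegmentationParams, segment_image
from cracksep.shape_analysis import describe_crack
from cracksep.synthetic import (
    CrackSpec,
    SceneSpec,
    generate_crack_image,
    generate_dataset,
    random_scene,
    rasterize_ellipse,
)


def test_rasterization_matches_direct_inequality():
    spec = CrackSpec(center=(30.0, 25.0), semi_major=10.0, semi_minor=3.0,
                     orientation_deg=0.0, intensity=200)
    coords = rasterize_ellipse(spec, (50, 60))
    expected = ellipse_pixels((30.0, 25.0), 10.0, 3.0, 0.0, (50, 60))
    assert set(map(tuple, coords.tolist())) == expected


def test_thresholding_noise_free_scene_recovers_ground_truth():
    scene = SceneSpec(
        shape=(60, 60), background_intensity=20, noise_sigma=0.0,
        cracks=(CrackSpec(center=(30.0, 30.0), semi_major=10.0, semi_minor=3.0,
                          orientation_deg=0.0, intensity=200),),
    )
    image, truth = generate_crack_image(scene)
    regions = segment_image(image, SegmentationParams(threshold=110))
    assert len(regions) == len(truth) == 1
    assert regions[0].pixel_set == set(map(tuple, truth[0].coords.tolist()))
    assert regions[0].area_px == truth[0].area_px


def test_noise_free_scene_is_seed_independent(simple_scene):
    img_a, _ = generate_crack_image(simple_scene)
    img_b, _ = generate_crack_image(
        SceneSpec(shape=simple_scene.shape,
                  background_intensity=simple_scene.background_intensity,
                  noise_sigma=0.0, cracks=simple_scene.cracks, seed=999)
    )
    assert np.array_equal(img_a.pixels, img_b.pixels)


def test_noisy_scene_is_reproducible_given_seed(simple_scene):
    noisy = SceneSpec(shape=simple_scene.shape, background_intensity=20,
                      noise_sigma=10.0, cracks=simple_scene.cracks, seed=7)
    img_a, _ = generate_crack_image(noisy)
    img_b, _ = generate_crack_image(noisy)
    assert np.array_equal(img_a.pixels, img_b.pixels)


def test_overlapping_cracks_rejected():
    cracks = (
        CrackSpec(center=(30.0, 30.0), semi_major=10.0, semi_minor=5.0,
                  orientation_deg=0.0),
        CrackSpec(center=(35.0, 30.0), semi_major=10.0, semi_minor=5.0,
                  orientation_deg=90.0),
    )
    with pytest.raises(SceneError, match="overlap"):
        generate_crack_image(SceneSpec(shape=(64, 64), cracks=cracks))


def test_ground_truth_orientation_tracks_spec():
    scene = SceneSpec(
        shape=(100, 100),
        cracks=(CrackSpec(center=(50.0, 50.0), semi_major=20.0, semi_minor=5.0,
                          orientation_deg=60.0),),
    )
    _, truth = generate_crack_image(scene)
    assert abs(truth[0].orientation_deg - 60.0) <= 2.0
    assert truth[0].anisotropy > 0.5


def test_random_scene_is_deterministic_and_disjoint():
    s1 = random_scene(seed=11, n_cracks=6)
    s2 = random_scene(seed=11, n_cracks=6)
    assert s1 == s2
    image, truth = generate_crack_image(s1)
    assert len(truth) == 6
    all_pixels = [tuple(p) for gt in truth for p in gt.coords.tolist()]
    assert len(all_pixels) == len(set(all_pixels))


def test_noisy_recovery_rate(rng):
    """With a >= 120 intensity gap and sigma <= 10, nearly all cracks survive."""
    recovered = expected = 0
    for seed in range(10):
        scene = random_scene(seed=seed, n_cracks=5, noise_sigma=10.0,
                             background_intensity=20, crack_intensity=200)
        image, truth = generate_crack_image(scene)
        regions = segment_image(
            image, SegmentationParams(threshold=110, min_area_px=10, max_area_px=10_000)
        )
        expected += len(truth)
        recovered += sum(
            1 for gt in truth
            if any(r.pixel_set >= set(map(tuple, gt.coords.tolist())) for r in regions)
            or any(len(r.pixel_set & set(map(tuple, gt.coords.tolist()))) /
                   gt.area_px > 0.9 for r in regions)
        )
    assert recovered / expected >= 0.95


def test_generate_dataset_round_trips_through_scanner(tmp_path):
    layout = {
        "mutA": [random_scene(seed=1, n_cracks=3, shape=(64, 64),
                              semi_major_range=(5.0, 9.0)) for _ in range(2)],
        "mutB": [random_scene(seed=2, n_cracks=3, shape=(64, 64),
                              semi_major_range=(5.0, 9.0))],
    }
    root = generate_dataset(tmp_path / "ds", layout, 110)
    index = scan_dataset(root)
    assert list(index.series) == ["mutA", "mutB"]
    assert [len(v) for v in index.series.values()] == [2, 1]
    assert all(e.threshold == 110 for v in index.series.values() for e in v)
    # one ground-truth sidecar per image
    assert len(list((root / "mutA").glob("*_groundtruth.csv"))) == 2


def test_generate_dataset_validates_threshold_and_layout(tmp_path):
    scene = random_scene(seed=1, n_cracks=2, shape=(64, 64), semi_major_range=(5.0, 8.0))
    with pytest.raises(NamingConventionError):
        generate_dataset(tmp_path / "x", {"s": [scene]}, 1000)
    with pytest.raises(SceneError):
        generate_dataset(tmp_path / "y", {}, 100)


def test_generate_dataset_refuses_nonempty_root(tmp_path):
    scene = random_scene(seed=1, n_cracks=2, shape=(64, 64), semi_major_range=(5.0, 8.0))
    root = tmp_path / "ds"
    root.mkdir()
    (root / "junk.txt").write_text("x")
    with pytest.raises(FileExistsError):
        generate_dataset(root, {"s": [scene]}, 100)
    generate_dataset(root, {"s": [scene]}, 100, overwrite=True)  # flag allows it


def test_invalid_crack_specs_rejected():
    with pytest.raises(SceneError):
        CrackSpec(center=(5.0, 5.0), semi_major=3.0, semi_minor=5.0, orientation_deg=0.0)
    with pytest.raises(SceneError):
        CrackSpec(center=(5.0, 5.0), semi_major=5.0, semi_minor=3.0, orientation_deg=200.0)
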