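"""Crop-schema geometry: boxes, upscaling, centring, retention, fallbacks."""

import numpy as np
import pytest

from oclnet.autoadapt import (
    AdaptConfig,
    BBox3D,
    adapt_dataset,
    crop_centered,
    mask_bounding_box,
    upscale_mask,
)
from oclnet.phantom import PhantomParams, generate_dataset
from oclnet.volume import MaskVolume, Volume


def _mask(shape, ones):
    m = np.zeros(shape, dtype=np.uint8)
    m[ones] = 1
    return MaskVolume(m)


def test_bbox_tight_and_empty_and_full():
    m = _mask((8, 8, 8), (slice(2, 5), slice(3, 7), slice(0, 2)))
    box = mask_bounding_box(m)
    assert box.lower == (2, 3, 0) and box.upper == (5, 7, 2)
    assert mask_bounding_box(MaskVolume(np.zeros((4, 4, 4), dtype=np.uint8))) is None
    full = mask_bounding_box(MaskVolume(np.ones((3, 4, 5), dtype=np.uint8)))
    assert full.lower == (0, 0, 0) and full.upper == (3, 4, 5)


def test_bbox_validation():
    with pytest.raises(ValueError):
        BBox3D((2, 2, 2), (2, 3, 3))


def test_upscale_factor_two_block():
    m = _mask((4, 4, 4), (1, 1, 1))
    up = upscale_mask(m, (8, 8, 8))
    expected = np.zeros((8, 8, 8), dtype=np.uint8)
    expected[2:4, 2:4, 2:4] = 1
    np.testing.assert_array_equal(up.data, expected)


def test_upscale_count_scales_by_volume_ratio(rng):
    m = MaskVolume((rng.random((5, 5, 5)) > 0.8).astype(np.uint8))
    count = m.num_foreground
    up = upscale_mask(m, (10, 15, 20))  # factors 2, 3, 4
    assert up.num_foreground == count * 2 * 3 * 4


def test_upscale_identity_and_downscale_rejection():
    m = _mask((4, 4, 4), (0, 1, 2))
    np.testing.assert_array_equal(upscale_mask(m, (4, 4, 4)).data, m.data)
    with pytest.raises(ValueError):
        upscale_mask(m, (2, 4, 4))


def _pair_with_lesion(shape=(64, 64, 64), at=(32, 32, 32), r=4):
    img = np.random.default_rng(0).random(shape).astype(np.float32)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    les = ((zz - at[0]) ** 2 + (yy - at[1]) ** 2 + (xx - at[2]) ** 2) <= r**2
    img[les] = 0.1
    return Volume(img), MaskVolume(les.astype(np.uint8))


def test_crop_interior_centroid_centred():
    img, lab = _pair_with_lesion()
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="D")
    box = mask_bounding_box(lab)
    ci, cl = crop_centered(img, lab, box, cfg)
    assert ci.shape == (32, 32, 32)
    out_centroid = np.argwhere(cl.data).mean(axis=0)
    assert np.abs(out_centroid - np.array([15.5, 15.5, 15.5])).max() <= 1.0
    assert cl.num_foreground == lab.num_foreground  # nothing lost


def test_crop_corner_pads_and_conserves_lesion():
    img, lab = _pair_with_lesion(at=(3, 3, 3), r=3)
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="D")
    box = mask_bounding_box(lab)
    ci, cl = crop_centered(img, lab, box, cfg)
    assert ci.shape == (32, 32, 32)
    assert cl.num_foreground == lab.num_foreground
    # padded faces carry the image minimum
    assert ci.data[0, 0, 0] == pytest.approx(float(img.data.min()))


def test_mode_s_preserves_input_size():
    img, lab = _pair_with_lesion(shape=(32, 32, 32), at=(16, 16, 16), r=3)
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="S")
    up = upscale_mask(lab, (64, 64, 64))
    ci, cl = crop_centered(img, lab, mask_bounding_box(up), cfg)
    assert ci.shape == (32, 32, 32) and cl.shape == (32, 32, 32)


def test_exact_fit_box_is_fully_contained():
    img, lab = _pair_with_lesion(shape=(16, 16, 16), at=(8, 8, 8), r=3)
    box = BBox3D((4, 4, 4), (8, 8, 8))  # size 4 == crop size
    cfg = AdaptConfig(upscale_shape=(16, 16, 16), crop_shape=(4, 4, 4), mode="D")
    _, cl = crop_centered(img, lab, box, cfg)
    inside = lab.data[4:8, 4:8, 4:8].sum()
    assert cl.num_foreground == inside


def test_none_bbox_keeps_whole_field_of_view():
    img, lab = _pair_with_lesion(shape=(64, 64, 64), at=(5, 58, 5), r=4)
    cfg = AdaptConfig(upscale_shape=(128, 128, 128), crop_shape=(64, 64, 64), mode="S")
    ci, cl = crop_centered(img, lab, None, cfg)
    assert ci.shape == (64, 64, 64)
    assert cl.num_foreground > 0  # peripheral lesion not cropped away


def _oracle(dataset):
    masks = {id(img.data): lab for img, lab in dataset}
    return lambda img: masks[id(img.data)]


def test_oracle_adaptation_retains_all_lesions():
    data = [
        (v, m)
        for v, m, p in generate_dataset(
            8, PhantomParams(shape=(32, 32, 32)), seed=3
        )
        if p != "large"  # large lesions can exceed the crop after upscaling
    ]
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="S")
    adapted, report = adapt_dataset(_oracle(data), data, cfg)
    for (img, lab) in adapted:
        assert img.shape == (32, 32, 32)
    assert report.fallback_fraction == 0.0
    assert all(r.lesion_retention == pytest.approx(1.0) for r in report.records)


def test_oracle_adaptation_reduces_background_fraction():
    data = [(v, m) for v, m, _ in generate_dataset(8, PhantomParams(shape=(32, 32, 32)), seed=3)]
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="S")
    adapted, _ = adapt_dataset(_oracle(data), data, cfg)
    before = np.mean([1 - m.num_foreground / m.data.size for _, m in data])
    after = np.mean([1 - m.num_foreground / m.data.size for _, m in adapted])
    assert after < before


def test_all_empty_predictions_fall_back():
    data = [(v, m) for v, m, _ in generate_dataset(4, PhantomParams(shape=(32, 32, 32)), seed=3)]
    empty = lambda img: MaskVolume(np.zeros((32, 32, 32), dtype=np.uint8))  # noqa: E731
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="S")
    adapted, report = adapt_dataset(empty, data, cfg)
    assert report.fallback_fraction == 1.0
    assert len(adapted) == 4
    for img, lab in adapted:
        assert img.shape == (32, 32, 32)
        assert lab.num_foreground > 0  # fallback keeps the lesion in view


def test_adaptation_idempotent_geometry():
    """Re-adapting oracle crops moves lesion centroids by at most one voxel."""
    data = [
        (v, m)
        for v, m, p in generate_dataset(6, PhantomParams(shape=(32, 32, 32)), seed=9)
        if p in ("small_crown", "small_apical")
    ]
    cfg = AdaptConfig(upscale_shape=(32, 32, 32), crop_shape=(32, 32, 32), mode="D")
    once, _ = adapt_dataset(_oracle(data), data, cfg)
    twice, _ = adapt_dataset(_oracle(once), once, cfg)
    for (_, l1), (_, l2) in zip(once, twice):
        c1 = np.argwhere(l1.data).mean(axis=0)
        c2 = np.argwhere(l2.data).mean(axis=0)
        assert np.abs(c1 - c2).max() <= 1.0


def test_report_csv_roundtrip(tmp_path):
    data = [(v, m) for v, m, _ in generate_dataset(4, PhantomParams(shape=(32, 32, 32)), seed=3)]
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="S")
    _, report = adapt_dataset(_oracle(data), data, cfg)
    path = report.write_csv(str(tmp_path / "report.csv"))
    lines = open(path).read().strip().splitlines()
    assert len(lines) == 5 and lines[0].startswith("index,")


def test_restore_to_native_roundtrips_oracle_crops():
    """Cropping with an oracle mask and mapping back recovers the lesion
    location on the native grid (small nearest-resample boundary loss)."""
    from oclnet.autoadapt import restore_to_native
    from oclnet.losses import dice_score

    data = [
        (v, m)
        for v, m, p in generate_dataset(8, PhantomParams(shape=(32, 32, 32)), seed=4)
        if p in ("small_apical", "medium")
    ]
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="S")
    adapted, report = adapt_dataset(_oracle(data), data, cfg)
    for (orig_img, orig_lab), (ci, cl), rec in zip(data, adapted, report.records):
        back = restore_to_native(cl, rec, cfg, orig_lab.shape)
        assert back.shape == orig_lab.shape
        assert dice_score(back.data, orig_lab.data) >= 0.85


def test_restore_to_native_fallback_path():
    from oclnet.autoadapt import restore_to_native
    from oclnet.losses import dice_score

    data = [(v, m) for v, m, _ in generate_dataset(2, PhantomParams(shape=(32, 32, 32)), seed=4)]
    empty = lambda img: MaskVolume(np.zeros((32, 32, 32), dtype=np.uint8))  # noqa: E731
    cfg = AdaptConfig(upscale_shape=(64, 64, 64), crop_shape=(32, 32, 32), mode="S")
    adapted, report = adapt_dataset(empty, data, cfg)
    for (orig_img, orig_lab), (_, cl), rec in zip(data, adapted, report.records):
        back = restore_to_native(cl, rec, cfg, orig_lab.shape)
        assert dice_score(back.data, orig_lab.data) >= 0.85
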