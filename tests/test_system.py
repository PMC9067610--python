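import numpy as np
import pytest
from dataclasses import replace

from speckleplane.diffusers import DiffuserSpec
from speckleplane.metrics import pcc
from speckleplane.objects import generate_digits, to_slm_pattern
from speckleplane.optics import ComplexField
from speckleplane.system import (
    capture,
    desk_config,
    generate_dataset,
    image_through_system,
    load_dataset,
    paper_config,
    save_dataset,
    split_indices,
    truth_on_camera,
)


@pytest.fixture(scope="module")
def cfg():
    return desk_config()


class TestConfig:
    def test_conjugate_distances(self, cfg):
        assert cfg.d_diffuser_conjugate == pytest.approx(cfg.f1)
        assert cfg.d_object_conjugate == pytest.approx(cfg.f1 - cfg.dist_slm_d2)

    def test_paper_geometry_as_published(self):
        p = paper_config()
        assert p.f1 == pytest.approx(0.150)
        assert p.f2 == pytest.approx(0.050)
        assert p.dist_d1_slm == pytest.approx(0.100)
        assert p.dist_slm_d2 == pytest.approx(0.080)
        assert p.iris_diameter == pytest.approx(7.5e-3)
        assert p.camera_crop == 256
        assert p.slm_active == 160
        assert p.d_object_conjugate == pytest.approx(0.070)
        assert p.d_diffuser_conjugate == pytest.approx(0.150)

    def test_grid_must_be_power_of_two(self, cfg):
        with pytest.raises(ValueError, match="power of two"):
            replace(cfg, grid=300)


class TestCapture:
    def test_uniform_field_maps_to_255(self, cfg):
        field = ComplexField(
            np.ones((cfg.grid, cfg.grid), complex), cfg.cam_pitch, cfg.wavelength
        )
        img = capture(field, cfg)
        assert img.dtype == np.uint8
        assert (img == 255).all()

    def test_scale_invariance(self, cfg):
        rng = np.random.default_rng(0)
        vals = rng.random((cfg.grid, cfg.grid)) + 0j
        f1 = ComplexField(vals, cfg.cam_pitch, cfg.wavelength)
        f2 = ComplexField(vals * 17.3, cfg.cam_pitch, cfg.wavelength)
        np.testing.assert_array_equal(capture(f1, cfg), capture(f2, cfg))

    def test_zero_field_gives_zero_image(self, cfg):
        f = ComplexField(np.zeros((cfg.grid, cfg.grid), complex), cfg.cam_pitch, cfg.wavelength)
        assert capture(f, cfg).sum() == 0

    def test_rounding_bound(self, cfg):
        rng = np.random.default_rng(1)
        vals = rng.random((cfg.grid, cfg.grid)) + 0j
        f = ComplexField(vals, cfg.cam_pitch, cfg.wavelength)
        img = capture(f, cfg)
        intensity = np.abs(vals) ** 2
        binf = max(1, round(cfg.cam_pitch / cfg.cam_pitch))
        crop = cfg.camera_crop * binf
        off = (cfg.grid - crop) // 2
        sub = intensity[off : off + crop, off : off + crop]
        binned = sub.reshape(cfg.camera_crop, binf, cfg.camera_crop, binf).mean(axis=(1, 3))
        exact = binned / binned.max() * 255.0
        assert np.abs(img.astype(float) - exact).max() <= 0.5


class TestImaging:
    def test_clear_system_images_object(self, cfg, digits20):
        c = replace(cfg, d=cfg.d_object_conjugate, iris_diameter=None)
        pat = to_slm_pattern(digits20[0], c.slm_active, c.grid)
        img = capture(image_through_system(pat, c), c)
        assert pcc(img, truth_on_camera(pat, c)) > 0.99

    def test_zero_pattern_zero_camera(self, cfg):
        from speckleplane.objects import AmplitudeObject

        obj = AmplitudeObject(np.zeros((32, 32)), label=0, id="z")
        pat = to_slm_pattern(obj, cfg.slm_active, cfg.grid)
        field = image_through_system(pat, cfg)
        assert np.abs(field.values).max() == 0.0

    def test_strong_diffuser_degrades_object_plane_pcc(self, cfg, digits20):
        c = replace(cfg, d=cfg.d_object_conjugate)
        vals_clear, vals_diff = [], []
        for seed in (0, 1, 2):
            screens = {}
            d2 = DiffuserSpec(4.0, seed=seed, name="strong")
            for obj in digits20[:3]:
                pat = to_slm_pattern(obj, c.slm_active, c.grid)
                tgt = truth_on_camera(pat, c)
                vals_clear.append(pcc(capture(image_through_system(pat, c), c), tgt))
                vals_diff.append(
                    pcc(capture(image_through_system(pat, c, d2=d2, _screens=screens), c), tgt)
                )
        assert np.mean(vals_diff) < np.mean(vals_clear)


class TestSplit:
    def test_ten_objects_split_7_2_1(self):
        s = split_indices(10)
        assert len(s["train"]) == 7
        assert len(s["val"]) == 2
        assert len(s["test"]) == 1

    def test_proportions_scale(self):
        s = split_indices(298)
        assert len(s["train"]) + len(s["val"]) + len(s["test"]) == 298
        assert len(s["train"]) > len(s["val"]) > len(s["test"])

    def test_tiny_dataset_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            split_indices(2)


class TestGenerateDataset:
    def test_contract_and_determinism(self, cfg):
        objs = generate_digits(10, size=32, seed=2)
        d2 = DiffuserSpec(4.0, seed=5, name="strong")
        a = generate_dataset(objs, cfg, d2=d2, master_seed=3)
        b = generate_dataset(objs, cfg, d2=d2, master_seed=3)
        assert len(a) == 10
        splits = [p.condition["split"] for p in a]
        assert splits.count("train") == 7
        assert splits.count("val") == 2
        assert splits.count("test") == 1
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.speckle, y.speckle)
        assert all(p.truth.label == o.label for p, o in zip(a, objs))

    def test_empty_objects_rejected(self, cfg):
        with pytest.raises(ValueError, match="empty"):
            generate_dataset([], cfg)

    def test_hdf5_round_trip(self, cfg, tmp_path):
        objs = generate_digits(5, size=32, seed=4)
        d2 = DiffuserSpec(4.0, seed=5, name="strong")
        pairs = generate_dataset(objs, cfg, d2=d2, master_seed=0)
        save_dataset(tmp_path / "d.h5", pairs, cfg)
        back, cfg2 = load_dataset(tmp_path / "d.h5")
        assert cfg2 == cfg
        assert len(back) == len(pairs)
        for p, q in zip(pairs, back):
            np.testing.assert_array_equal(p.speckle, q.speckle)
            np.testing.assert_array_equal(p.target, q.target)
            assert p.condition == q.condition
            assert p.truth.label == q.truth.label
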