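"""Config validation, image I/O, and the CLI round trip."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import nodereg as nr
from nodereg import fixtures as fx
from nodereg.cli import main
from nodereg.config import RunConfig, load_config, load_image


@pytest.fixture()
def disc_pair_files(tmp_path):
    pair = fx.disc_translation(resolution=64, shift=(0.15, 0.0))
    src, tgt = tmp_path / "src.npy", tmp_path / "tgt.npy"
    np.save(src, pair["S1"].coefficients)
    np.save(tgt, pair["S2"].coefficients)
    return src, tgt, pair


class TestConfig:
    def test_defaults_validate(self):
        cfg = RunConfig(source="a.png", target="b.png")
        cfg.validate()
        assert cfg.learning_rate == 5e-5
        assert cfg.n_steps == 15
        assert cfg.material == {"kind": "stvk", "mu": 1.0, "lambda": 1.0}

    def test_missing_paths_rejected(self):
        with pytest.raises(ValueError, match="source/target"):
            RunConfig().validate()

    def test_bad_material_rejected(self):
        cfg = RunConfig(source="a", target="b",
                        material={"kind": "rubber"})
        with pytest.raises(ValueError, match="rubber"):
            cfg.validate()

    def test_unknown_yaml_keys_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text(yaml.safe_dump({"sorce": "a.png"}))
        with pytest.raises(ValueError, match="unknown keys"):
            load_config(p)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text(yaml.safe_dump({
            "source": "s.npy", "target": "t.npy", "seed": 42,
            "growth": {"mode": "shrinkage", "kappa_init": 0.01}}))
        cfg = load_config(p)
        assert cfg.seed == 42
        g = cfg.growth_obj()
        assert g.mode == "shrinkage"


class TestImageIO:
    def test_npy_roundtrip(self, tmp_path, disc_field):
        p = tmp_path / "f.npy"
        np.save(p, disc_field.coefficients)
        f = load_image(p, 0.5)
        assert f.grid_shape == disc_field.grid_shape
        assert np.array_equal(f.coefficients, disc_field.coefficients)

    def test_png_roundtrip_preserves_mask(self, tmp_path, disc_field):
        from PIL import Image
        img = (disc_field.coefficients * 255).astype(np.uint8)
        # writer convention used by the CLI: axis 0 = x, axis 1 = y up
        Image.fromarray(img[:, ::-1].T).save(tmp_path / "f.png")
        f = load_image(tmp_path / "f.png", 0.5)
        assert np.array_equal(f.coefficients, disc_field.coefficients)

    def test_nifti_geometry(self, tmp_path):
        import nibabel as nib
        arr = np.zeros((8, 9, 10), dtype=np.float32)
        arr[3:6, 3:6, 3:6] = 1.0
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = [-8, -9, -10]
        nib.save(nib.Nifti1Image(arr, aff), str(tmp_path / "v.nii.gz"))
        f = load_image(tmp_path / "v.nii.gz", 0.5)
        assert np.allclose(f.spacing, 2.0)
        assert np.allclose(f.origin, [-8, -9, -10])


class TestCli:
    def test_register_writes_bundle(self, tmp_path, disc_pair_files):
        src, tgt, _ = disc_pair_files
        out = tmp_path / "run"
        cfgp = tmp_path / "cfg.yaml"
        cfgp.write_text(yaml.safe_dump({
            "source": str(src), "target": str(tgt),
            "output_dir": str(out), "elements": [30, 30],
            "epochs_predictor": 40, "epochs_corrector": 30,
            "batch_predictor": 200, "batch_corrector": 150,
            "learning_rate": 0.0005, "seed": 5}))
        res = CliRunner().invoke(main, ["register", str(cfgp)])
        assert res.exit_code == 0, res.output
        summary = json.loads((out / "summary.json").read_text())
        assert "dice_predictor" in summary and "dice_corrector" in summary
        assert (out / "predictor.npz").exists()
        assert (out / "traces.csv").exists()

    def test_skip_corrector_flag(self, tmp_path, disc_pair_files):
        src, tgt, _ = disc_pair_files
        out = tmp_path / "run2"
        cfgp = tmp_path / "cfg.yaml"
        cfgp.write_text(yaml.safe_dump({
            "source": str(src), "target": str(tgt),
            "output_dir": str(out), "elements": [25, 25],
            "epochs_predictor": 20, "batch_predictor": 150,
            "seed": 5}))
        res = CliRunner().invoke(main, ["register", str(cfgp),
                                        "--skip-corrector"])
        assert res.exit_code == 0, res.output
        summary = json.loads((out / "summary.json").read_text())
        assert "dice_corrector" not in summary
        assert not (out / "corrector.npz").exists()

    def test_invalid_config_nonzero_exit(self, tmp_path):
        cfgp = tmp_path / "bad.yaml"
        cfgp.write_text(yaml.safe_dump({"beta": -1.0}))
        res = CliRunner().invoke(main, ["register", str(cfgp)])
        assert res.exit_code != 0

    def test_evaluate_identity_checkpoint(self, tmp_path, disc_pair_files):
        src, _, _ = disc_pair_files
        net = nr.VelocityNetwork.create(2, (8, 8, 8),
                                        np.random.default_rng(0))
        ck = tmp_path / "ident.npz"
        nr.save_checkpoint(ck, nr.FlowMap(net))
        res = CliRunner().invoke(main, [
            "evaluate", str(ck), "--source", str(src), "--target", str(src),
            "--out", str(tmp_path / "ev")])
        assert res.exit_code == 0, res.output
        metrics = json.loads((tmp_path / "ev" / "metrics.json").read_text())
        assert metrics["dice"] == 1.0

    def test_evaluate_missing_checkpoint(self, tmp_path, disc_pair_files):
        src, tgt, _ = disc_pair_files
        res = CliRunner().invoke(main, [
            "evaluate", str(tmp_path / "nope.npz"),
            "--source", str(src), "--target", str(tgt)])
        assert res.exit_code != 0
        assert "not found" in res.output

    def test_make_fixture_writes_pngs(self, tmp_path):
        res = CliRunner().invoke(main, [
            "make-fixture", "disc_translation", "--out", str(tmp_path),
            "--resolution", "48"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "disc_translation_S1.png").exists()
        assert (tmp_path / "disc_translation_S2.png").exists()

    def test_sequence_of_identical_frames(self, tmp_path, disc_pair_files):
        src, _, _ = disc_pair_files
        out = tmp_path / "seq"
        cfgp = tmp_path / "cfg.yaml"
        cfgp.write_text(yaml.safe_dump({
            "sequence": [str(src)] * 3, "output_dir": str(out),
            "elements": [25, 25], "epochs_predictor": 25,
            "batch_predictor": 150, "skip_corrector": True,
            "learning_rate": 0.0003, "seed": 2}))
        res = CliRunner().invoke(main, ["register-sequence", str(cfgp)])
        assert res.exit_code == 0, res.output
        summary = json.loads((out / "sequence_summary.json").read_text())
        assert all(d >= 0.99 for d in summary["dice_per_step"])
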