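import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import tifffile
import yaml
from click.testing import CliRunner

from focipipe.aggregate import QCRules
from focipipe.synthetic_scenes import SceneParams, generate_plate
from focipipe.workbench import (
    AnalysisSettings,
    PlateLayout,
    RunConfig,
    analyze_position,
    main,
    normalize_well,
    run_pipeline,
    run_screen,
    sirna_final_concentration,
)


class TestWellNormalization:
    @pytest.mark.parametrize("raw,norm", [("A1", "A01"), ("a01", "A01"), ("H12", "H12")])
    def test_normalize(self, raw, norm):
        assert normalize_well(raw) == norm

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            normalize_well("1A")


class TestPlateLayout:
    def test_duplicate_well_rejected(self):
        layout = PlateLayout("p")
        layout.add("A1", "X", role="library")
        with pytest.raises(ValueError, match="duplicate"):
            layout.add("A01", "Y", role="library")

    def test_csv_roundtrip(self, tmp_path, small_layout):
        path = tmp_path / "layout.csv"
        small_layout.to_csv(path)
        back = PlateLayout.from_csv(path)
        assert back.wells == small_layout.wells

    def test_scoring_validation(self):
        layout = PlateLayout("p")
        layout.add("A01", "X", role="library")
        layout.add("H01", "sNEG1", role="sNEG1")
        with pytest.raises(ValueError, match="sNEG1"):
            layout.validate_for_scoring()

    def test_unknown_role_rejected(self):
        layout = PlateLayout("p")
        with pytest.raises(ValueError, match="role"):
            layout.add("A01", "X", role="mystery")


class TestConcentrationCalculator:
    def test_primary_protocol(self):
        # 5 ul of 3 uM siRNA into a 19 ul mix, 1:51 dilution, 50 ul per
        # well, 100 ul medium
        conc = sirna_final_concentration(3000, 5, 19, 51, 50, 100)
        assert conc == pytest.approx(7.7)

    def test_secondary_protocol(self):
        # 25 ul of 100 nM siRNA in a 25+8+207 = 240 ul final well volume
        conc = sirna_final_concentration(100, 25, 240, 1, 240, 240)
        assert conc == pytest.approx(10.4)

    def test_no_dilution_identity(self):
        conc = sirna_final_concentration(300, 10, 30, 1, 30, 30, ndigits=None)
        assert conc == pytest.approx(300 * 10 / 30)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sirna_final_concentration(0, 5, 19, 51, 50, 100)


class TestRunConfig:
    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"screen": "primary", "bogus": 1}))
        with pytest.raises(ValueError, match="unknown config keys"):
            RunConfig.from_yaml(path)

    def test_roundtrip_metadata(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        cfg = {"screen": "secondary", "seed": 7, "pseudocount": 0.0625}
        path.write_text(yaml.safe_dump(cfg))
        rc = RunConfig.from_yaml(path)
        meta = rc.to_metadata()
        assert meta["screen"] == "secondary" and meta["seed"] == 7
        assert RunConfig(**{k: v for k, v in meta.items()}).settings().screen == "secondary"

    def test_settings_profiles(self):
        assert AnalysisSettings.for_screen("primary").foci_profile.name == "primary"
        assert AnalysisSettings.for_screen("secondary").segmentation.max_diameter == 43
        with pytest.raises(ValueError):
            AnalysisSettings.for_screen("tertiary")


PERMISSIVE = QCRules(min_growth_slope=None)


def _tiny_plate(layout, seed=11, n_positions=2, n_replicates=1):
    base = SceneParams(
        image_shape=(256, 256), n_cells=5, n_frames=4, nucleus_radius_mean=22,
        late_s_fraction=0.7, noise_sd=0.003, cell_drift_sd=1.5, seed=0,
    )
    return generate_plate(layout, base, n_positions=n_positions, seed=seed,
                          n_replicates=n_replicates)


class TestPipeline:
    def test_analyze_position_counts(self, foci_scene):
        tl, truth = foci_scene
        settings = AnalysisSettings.for_screen("primary", qc_rules=PERMISSIVE)
        pa = analyze_position(tl.frames, settings, frame_interval=tl.frame_interval)
        assert pa.n_tracks == len(truth.cells)
        assert pa.readout is not None
        assert pa.qc.passed
        assert len(pa.plls) == tl.n_frames

    def test_channel_stack_rejected(self):
        settings = AnalysisSettings.for_screen("primary")
        with pytest.raises(ValueError, match="stack"):
            analyze_position(np.zeros((2, 3, 32, 32)), settings)

    def test_run_screen_bookkeeping_and_determinism(self, small_layout):
        ds = _tiny_plate(small_layout)
        settings = AnalysisSettings.for_screen("primary", qc_rules=PERMISSIVE)
        sr1 = run_screen(ds, settings)
        sr2 = run_screen(ds, settings)
        # one row per distinct library siRNA
        assert list(sr1.sirna.sirna) == ["LIB1"]
        pd.testing.assert_frame_equal(sr1.sirna, sr2.sirna)
        pd.testing.assert_frame_equal(sr1.positions, sr2.positions)

    def test_run_pipeline_end_to_end(self, tmp_path, small_layout):
        ds = _tiny_plate(small_layout)
        in_dir = tmp_path / "in"
        in_dir.mkdir()
        small_layout.to_csv(in_dir / "layout.csv")
        for pos in ds:
            stem = f"r{pos.replicate}_{pos.well}_p{pos.position}"
            tifffile.imwrite(in_dir / f"{stem}.tif", pos.timelapse.frames)
        cfg = RunConfig(
            input_dir=str(in_dir), output_dir=str(tmp_path / "out"),
            qc={"min_growth_slope": None}, seed=1,
        )
        sr = run_pipeline(cfg)
        out = tmp_path / "out"
        assert (out / "positions.csv").exists()
        assert (out / "sirna_scores.csv").exists()
        meta = json.loads((out / "run_metadata.json").read_text())
        assert meta["config"]["seed"] == 1
        assert len(sr.sirna) == 1


class TestOverlay:
    def test_overlay_written(self, tmp_path, foci_scene):
        from focipipe.foci import PRIMARY_FOCI, detect_foci
        from focipipe.nuclei import PRIMARY_SEGMENTATION, segment_nuclei
        from focipipe.preprocess import subtract_background
        from focipipe.workbench import save_overlay

        tl, _ = foci_scene
        corrected, _ = subtract_background(tl.frames[0])
        nuclei = segment_nuclei(corrected, PRIMARY_SEGMENTATION)
        spots = detect_foci(corrected, nuclei, PRIMARY_FOCI)
        out = tmp_path / "overlay.png"
        save_overlay(out, corrected, nuclei, spots)
        import imageio.v3 as iio

        img = iio.imread(out)
        assert img.ndim == 3 and img.shape[2] == 3
        # foci rings are drawn in pure red
        assert ((img[..., 0] == 255) & (img[..., 1] == 0)).any()


class TestCli:
    def test_conc_command(self):
        runner = CliRunner()
        res = runner.invoke(
            main,
            ["conc", "--stock-conc", "3000", "--stock-vol", "5", "--mix-vol", "19",
             "--dilution-factor", "51", "--dispensed-vol", "50", "--medium-vol", "100"],
        )
        assert res.exit_code == 0
        assert "7.7" in res.output

    def test_simulate_and_score_commands(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "sim"
        res = runner.invoke(
            main,
            ["simulate", "--out", str(out_dir), "--seed", "3", "--wells", "1",
             "--positions", "1", "--cells", "4", "--frames", "3"],
        )
        assert res.exit_code == 0, res.output
        assert (out_dir / "layout.csv").exists()
        assert (out_dir / "ground_truth.csv").exists()
        assert list(out_dir.glob("*.tif"))

    def test_frap_command(self, tmp_path):
        t = np.linspace(0, 60, 100)
        y = 0.8 * (1 - np.exp(-t / 10.0))
        csv = tmp_path / "curve.csv"
        pd.DataFrame({"t": t, "I": y}).to_csv(csv, index=False)
        runner = CliRunner()
        res = runner.invoke(main, ["frap", "--csv", str(csv)])
        assert res.exit_code == 0, res.output
        assert json.loads(res.output)["tau"] == pytest.approx(10.0, abs=0.05)
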