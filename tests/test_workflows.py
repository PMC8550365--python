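import json
import os

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ramanci import SynthConfig, write_xy_table
from ramanci.cli import main as cli_main
from ramanci.crystallinity import save_amorphous_reference
from ramanci.errors import ConfigError
from ramanci.preprocess import preprocess_pipeline
from ramanci.spectra_io import SpectrumSet, read_xy_table
from ramanci.synth import (
    synth_blend_series,
    synth_diffraction_blank,
    synth_diffractogram,
)
from ramanci.crystallinity import build_amorphous_reference
from ramanci.workflows import (
    RunConfig,
    calibration_study,
    workflow_calibrate,
    workflow_ci380,
    workflow_model,
    workflow_pca,
)
from ramanci.synth import synth_batch_panel


class TestCalibrationStudy:
    def test_noise_free_recovery_within_half_point(self):
        study = calibration_study(SynthConfig(seed=7), noise_sd_frac=0.0)
        assert np.max(np.abs(study.recovery_error())) < 0.5
        assert study.calibration.pearson_r > 0.999

    def test_ratio_affine_in_fraction_noise_free(self):
        study = calibration_study(SynthConfig(seed=7), noise_sd_frac=0.0)
        chi = np.asarray(study.fractions)
        r2 = np.corrcoef(chi, study.mean_ratio)[0, 1] ** 2
        assert r2 > 0.999
        order = np.argsort(chi)
        assert np.all(np.diff(study.mean_ratio[order]) > 0)

    def test_noisy_recovery_at_study_conditions(self):
        study = calibration_study(SynthConfig(seed=7), noise_sd_frac=0.01)
        assert np.max(np.abs(study.recovery_error())) < 3.0
        assert study.calibration.pearson_r > 0.99

    def test_deterministic_given_config(self):
        a = calibration_study(SynthConfig(seed=13), noise_sd_frac=0.01)
        b = calibration_study(SynthConfig(seed=13), noise_sd_frac=0.01)
        assert np.array_equal(a.predicted_ci, b.predicted_ci)


@pytest.fixture(scope="module")
def blend_files(tmp_path_factory):
    """Noise-free blend series + diffractograms + amorphous ref on disk."""
    root = tmp_path_factory.mktemp("blends")
    cfg = SynthConfig(seed=21)
    specs, truths = synth_blend_series(n_replicates=2, cfg=cfg,
                                       noise_sd_frac=0.0)
    for s in specs:
        write_xy_table(s, root / f"{s.sample_id}_r{s.replicate}.csv")
    for bi, f in enumerate(sorted({t.chi for t in truths}, reverse=True)):
        d, _ = synth_diffractogram(f, cfg, noise=False, seed_counters=(5, bi))
        write_xy_table(d, root / f"pxrd_{int(round(100 * f)):03d}.csv")
    write_xy_table(synth_diffraction_blank(cfg, noise=False),
                   root / "blank.csv")
    refs, _ = synth_blend_series([0.0], 5, cfg, noise_sd_frac=0.0,
                                 seed_stream=2)
    ref = build_amorphous_reference(
        SpectrumSet([preprocess_pipeline(s) for s in refs]))
    save_amorphous_reference(ref, root / "amorphous_ref.json")
    chi = sorted({t.chi for t in truths}, reverse=True)
    return root, chi


class TestFileWorkflows:
    def test_calibrate_then_ci380_recovers_fractions(self, blend_files, tmp_path):
        root, chi = blend_files
        cfg = RunConfig(inputs=[str(root / "blend_*_r*.csv")],
                        amorphous_ref=str(root / "amorphous_ref.json"),
                        out_dir=str(tmp_path), probe="OTHER")
        cal = workflow_calibrate(cfg, [str(root / "pxrd_*.csv")],
                                 blank=str(root / "blank.csv"))
        assert cal.pearson_r > 0.999
        cfg2 = RunConfig(inputs=[str(root / "blend_*_r*.csv")],
                         calibration=os.path.join(str(tmp_path), "calibration.json"),
                         amorphous_ref=str(root / "amorphous_ref.json"),
                         out_dir=str(tmp_path))
        table = workflow_ci380(cfg2)
        assert (table["flag"] == "").all()
        for f in chi:
            got = table.loc[table["sample_id"].str.startswith(
                f"blend_{int(round(100 * f)):03d}"), "ci_pct"]
            assert np.allclose(got, 100 * f, atol=0.5)
        # provenance written
        assert os.path.exists(tmp_path / "ci380_provenance.json")

    def test_empty_glob_is_config_error(self, tmp_path):
        cfg = RunConfig(inputs=[str(tmp_path / "nope_*.csv")],
                        calibration="MR", amorphous_ref="x.json")
        with pytest.raises(ConfigError):
            workflow_ci380(cfg)

    def test_two_blends_only_is_config_error(self, blend_files, tmp_path):
        root, _ = blend_files
        cfg = RunConfig(inputs=[str(root / "blend_100_r*.csv"),
                                str(root / "blend_083_r*.csv")],
                        amorphous_ref=str(root / "amorphous_ref.json"),
                        out_dir=str(tmp_path))
        with pytest.raises(ConfigError, match=">= 3 blends"):
            workflow_calibrate(cfg, [str(root / "pxrd_100.csv"),
                                     str(root / "pxrd_083.csv")])

    def test_modality_count_mismatch_is_config_error(self, blend_files, tmp_path):
        root, _ = blend_files
        cfg = RunConfig(inputs=[str(root / "blend_*_r*.csv")],
                        amorphous_ref=str(root / "amorphous_ref.json"),
                        out_dir=str(tmp_path))
        with pytest.raises(ConfigError, match="diffractograms"):
            workflow_calibrate(cfg, [str(root / "pxrd_100.csv")])


@pytest.fixture(scope="module")
def panel_files(tmp_path_factory):
    """A spanned-design synthetic panel written to disk with its y table."""
    root = tmp_path_factory.mktemp("panel")
    panel = synth_batch_panel(30, (0.5, 0.9), cfg=SynthConfig(seed=7))
    rows = []
    for s, t, b in zip(panel.spectra, panel.truths, panel.batch_of):
        name = f"{b}_{s.probe}_r{s.replicate}.csv"
        write_xy_table(s, root / name)
        rows.append({"sample_id": name[:-4], "ci": 100 * t.chi, "batch": b})
    pd.DataFrame(rows).drop_duplicates("sample_id").to_csv(
        root / "y.csv", index=False)
    return root, pd.DataFrame(rows)


class TestModelWorkflow:
    def test_fit_then_predict_beats_no_information(self, panel_files, tmp_path):
        root, table = panel_files
        batches = sorted(table["batch"].unique())
        cal_files = [str(root / f"{r.sample_id}.csv")
                     for r in table.itertuples() if r.batch in batches[:24]]
        val_files = [str(root / f"{r.sample_id}.csv")
                     for r in table.itertuples() if r.batch in batches[24:]]
        fit_cfg = RunConfig(inputs=cal_files, y_table=str(root / "y.csv"),
                            max_factors=5, out_dir=str(tmp_path))
        groups = [table.set_index("sample_id")["batch"][os.path.basename(f)[:-4]]
                  for f in cal_files]
        stats = workflow_model(fit_cfg, "fit", groups=groups)
        assert np.all(np.diff(stats["rmsec"]) <= 1e-9)
        pred_cfg = RunConfig(inputs=val_files,
                             model_file=str(tmp_path / "pls_model.json"),
                             n_factors=3, y_table=str(root / "y.csv"),
                             out_dir=str(tmp_path))
        out = workflow_model(pred_cfg, "predict")
        resid = out["predicted_ci_pct"] - out["reference_ci_pct"]
        rmsep = float(np.sqrt(np.mean(resid**2)))
        no_info = float(out["reference_ci_pct"].std(ddof=1))
        assert rmsep < no_info
        with open(tmp_path / "pls_predict_provenance.json") as fh:
            prov = json.load(fh)
        assert prov["explained_val_pct"] > 90.0

    def test_single_latent_factor_panel_is_explained_by_one_factor(
            self, tmp_path, rng):
        # y proportional to the single spectral contrast present
        from ramanci import pls1_fit
        chi = rng.uniform(0, 1, 20)
        grid = np.linspace(0, 1, 40)
        direction = np.exp(-0.5 * ((grid - 0.3) / 0.05) ** 2)
        X = np.outer(chi, direction)
        model = pls1_fit(X, 100 * chi, 1)
        assert model.explained_cal[0] > 99.0


class TestPCAWorkflow:
    def test_two_probe_panel_separates_by_one_score_threshold(self, tmp_path):
        panel = synth_batch_panel(30, cfg=SynthConfig(seed=7))
        root = tmp_path / "spectra"
        root.mkdir()
        for s, b in zip(panel.spectra, panel.batch_of):
            write_xy_table(s, root / f"{b}_{s.probe}_r{s.replicate}.csv")
        cfg = RunConfig(inputs=[str(root / "*.csv")], out_dir=str(tmp_path))
        groups = [os.path.basename(str(p)).split("_MR")[0].split("_PHAT")[0]
                  for p in sorted(root.iterdir())]
        scores = workflow_pca(cfg, n_components=2, groups=groups)
        probes = ["MR" if "_MR_" in sid else "PHAT"
                  for sid in scores["sample_id"]]
        separable = False
        for col in ("PC1", "PC2"):
            a = scores.loc[[p == "MR" for p in probes], col]
            b = scores.loc[[p == "PHAT" for p in probes], col]
            if a.max() < b.min() or b.max() < a.min():
                separable = True
        assert separable
        assert os.path.exists(tmp_path / "pca_correlation_loadings.csv")

    def test_single_group_skips_cv_with_warning(self, tmp_path):
        panel = synth_batch_panel(2, cfg=SynthConfig(seed=3))
        root = tmp_path / "s"
        root.mkdir()
        for s in panel.spectra:
            write_xy_table(s, root / f"{s.sample_id}_{s.probe}_r{s.replicate}.csv")
        cfg = RunConfig(inputs=[str(root / "*.csv")], out_dir=str(tmp_path))
        with pytest.warns(UserWarning, match="cross-validation skipped"):
            workflow_pca(cfg, n_components=2,
                         groups=["only"] * len(panel.spectra))
        summary = pd.read_csv(tmp_path / "pca_variance.csv")
        assert summary["explained_cal_pct"].notna().all()


class TestCLI:
    def test_simulate_segal_preprocess_chain(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(cli_main, [
            "simulate", "blends", "--replicates", "1", "--seed", "5",
            "--fractions", "1.0,0.5,0.0", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "ground_truth.csv").exists()
        r = runner.invoke(cli_main, [
            "segal", "--in", str(out / "pxrd_100.csv"),
            "--blank", str(out / "blank.csv")])
        assert r.exit_code == 0
        assert float(r.output.strip()) > 95.0
        r = runner.invoke(cli_main, [
            "preprocess", "--in", str(out / "blend_100_r1.csv"),
            "--out", str(tmp_path / "pp")])
        assert r.exit_code == 0
        pp = read_xy_table(tmp_path / "pp" / "blend_100_r1_pp.csv")
        assert abs(pp.intensities.mean()) < 1e-9

    def test_missing_input_exits_with_config_code(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "ci380", "--in", str(tmp_path / "none*.csv"),
            "--calibration", "MR",
            "--amorphous-ref", str(tmp_path / "ref.json")])
        assert r.exit_code == 2
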