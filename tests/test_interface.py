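"""File formats, session round-trips, pipeline composition and the CLI."""

import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from dyadsync import io as dio
from dyadsync.cli import main as cli_main
from dyadsync.errors import ConfigurationError, InputError, LayoutError, ParseError
from dyadsync.pipeline import PipelineConfig, run_pipeline, write_results
from dyadsync.simulate import SyntheticConfig, generate_classroom


@pytest.fixture(scope="module")
def session_dir(tmp_path_factory):
    cfg = SyntheticConfig(n_dyads_per_class=[2, 2], session_length_s=1200.0, seed=31)
    classroom = generate_classroom(cfg)
    out = tmp_path_factory.mktemp("session")
    dio.write_classroom(classroom, out)
    return classroom, out


class TestRoundTrip:
    def test_written_session_reads_back_equal(self, session_dir):
        classroom, out = session_dir
        session = dio.read_session(out)
        assert session["layout"].dyads == classroom.layout.dyads
        assert session["layout"].class_of == classroom.layout.class_of
        assert session["reports"] == classroom.reports
        for pid, beats in classroom.beat_series.items():
            np.testing.assert_allclose(session["beats"][pid], beats, atol=1e-6)

    def test_annotations_cover_protocol_segments(self, session_dir):
        _, out = session_dir
        ann = dio.read_annotations(out / "annotations.csv")
        assert ann[0][0] == "baseline" and ann[0][1] == 0.0
        assert ann[-1][2] == pytest.approx(1200.0)

    def test_ecg_csv_roundtrip(self, tmp_path):
        from dyadsync.simulate import synthesize_ecg

        x, fs = synthesize_ecg(np.array([1.0, 2.0]), 250.0, duration_s=12.0, rng=0)
        dio.write_ecg_csv(x, fs, tmp_path / "ecg_p1.csv")
        rec = dio.read_ecg_csv(tmp_path / "ecg_p1.csv", 1)
        assert rec.sampling_rate == pytest.approx(fs, rel=1e-6)
        np.testing.assert_allclose(rec.samples, np.round(x, 5), atol=1e-9)


class TestValidation:
    def test_layout_referencing_absent_participant(self, session_dir, tmp_path):
        _, out = session_dir
        for f in out.iterdir():
            (tmp_path / f.name).write_text(f.read_text())
        (tmp_path / "beats_p1.csv").unlink()
        with pytest.raises(InputError, match=r"\b1\b"):
            dio.read_session(tmp_path)

    def test_non_numeric_voltage_cell_reports_line(self, tmp_path):
        path = tmp_path / "ecg_p1.csv"
        path.write_text("time_s,mv\n0.000,0.1\n0.004,oops\n0.008,0.3\n")
        with pytest.raises(ParseError, match="line 3"):
            dio.read_ecg_csv(path, 1)

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "layout.csv"
        path.write_text("dyad_id,first_id,second_id\n0,1,2\n")
        with pytest.raises(ParseError, match="class_id"):
            dio.read_layout(path)

    def test_feature_tsv_roundtrip(self, session_dir, tmp_path):
        classroom, _ = session_dir
        from dyadsync.ecg import beats_to_nn
        from dyadsync.hrv import WindowSpec, feature_matrix

        fvs = []
        for pid, beats in classroom.beat_series.items():
            fvs.extend(feature_matrix(beats_to_nn(pid, beats), WindowSpec(300.0)).values())
        dio.write_feature_tsv(fvs, tmp_path / "features.tsv")
        back = dio.read_feature_tsv(tmp_path / "features.tsv")
        key = ("SDNN", 300.0)
        orig = {fv.participant_id: fv for fv in fvs if fv.feature == "SDNN"}
        for pid, fv in back[key].items():
            np.testing.assert_allclose(fv.values, orig[pid].values, atol=1e-6)
            np.testing.assert_array_equal(fv.valid_mask, orig[pid].valid_mask)


class TestRunPipeline:
    def test_full_result_shape(self, session_dir):
        classroom, _ = session_dir
        cfg = PipelineConfig(
            window_lengths=(60, 100, 140, 180, 220, 260, 300),
            n_permutations=200,
            seed=5,
            regression_windows=(),
        )
        res = run_pipeline(classroom.layout, beats=classroom.beat_series, config=cfg)
        assert len(res.compliance) == 21  # 3 features x 7 window lengths
        assert len(res.permutation) == 21
        for key, perm in res.permutation.items():
            assert perm.p_adjusted is not None
            assert perm.p_adjusted >= perm.p_raw - 1e-15

    def test_fixed_seed_gives_byte_identical_output(self, session_dir, tmp_path):
        classroom, _ = session_dir
        cfg = PipelineConfig(window_lengths=(300,), n_permutations=200, seed=9,
                             regression_windows=())
        outs = []
        for d in ("a", "b"):
            res = run_pipeline(
                classroom.layout, beats=classroom.beat_series,
                reports=classroom.reports, config=cfg,
            )
            write_results(res, tmp_path / d)
            outs.append((tmp_path / d / "permutation.json").read_bytes())
        assert outs[0] == outs[1]

    def test_empty_layout_fails_fast(self, session_dir):
        classroom, _ = session_dir
        with pytest.raises(LayoutError):
            from dyadsync.compliance import ClassroomLayout

            ClassroomLayout([])

    def test_missing_data_for_layout_participant(self, session_dir):
        classroom, _ = session_dir
        beats = dict(classroom.beat_series)
        beats.pop(classroom.layout.dyads[0][0])
        with pytest.raises(InputError, match="without data"):
            run_pipeline(classroom.layout, beats=beats,
                         config=PipelineConfig(window_lengths=(300,), n_permutations=100))

    def test_invalid_pipeline_config_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig(window_lengths=(30,))
        with pytest.raises(ConfigurationError):
            PipelineConfig(n_permutations=10)


class TestCli:
    def test_stagewise_composition_equals_all_in_one(self, tmp_path):
        """simulate -> features -> compliance -> permtest -> regress == all."""
        runner = CliRunner()
        sess = tmp_path / "sess"
        staged = tmp_path / "staged"
        oneshot = tmp_path / "oneshot"
        common = ["--windows", "300", "--seed", "4"]

        r = runner.invoke(cli_main, [
            "simulate", "--out", str(sess), "--seed", "13",
            "--dyads", "4,4", "--session-length", "1200",
        ])
        assert r.exit_code == 0, r.output
        for args in (
            ["features", "--in", str(sess), "--out", str(staged), *common],
            ["compliance", "--in", str(sess), "--features", str(staged / "features.tsv"),
             "--out", str(staged)],
            ["permtest", "--in", str(sess), "--features", str(staged / "features.tsv"),
             "--out", str(staged), "--n-perms", "200", "--seed", "4"],
            ["regress", "--in", str(sess), "--compliance", str(staged / "compliance.tsv"),
             "--out", str(staged), "--windows", "300"],
            ["all", "--in", str(sess), "--out", str(oneshot), "--n-perms", "200", *common],
        ):
            r = runner.invoke(cli_main, args)
            assert r.exit_code == 0, f"{args}: {r.output}"

        staged_perm = json.loads((staged / "permutation.json").read_text())
        oneshot_perm = json.loads((oneshot / "permutation.json").read_text())
        assert staged_perm == oneshot_perm
        assert (staged / "compliance.tsv").read_text() == (oneshot / "compliance.tsv").read_text()
        assert (staged / "regression.tsv").read_text() == (oneshot / "regression.tsv").read_text()

    def test_simulate_with_ecg_waveforms_feeds_detection(self, tmp_path):
        runner = CliRunner()
        sess = tmp_path / "sess"
        r = runner.invoke(cli_main, [
            "simulate", "--out", str(sess), "--seed", "3", "--dyads", "1",
            "--session-length", "400", "--ecg", "--fs", "250",
        ])
        assert r.exit_code == 0, r.output
        assert (sess / "ecg_p1.csv").exists()
        session = dio.read_session(sess)
        assert set(session["recordings"]) == {1, 2}
        out = tmp_path / "out"
        r = runner.invoke(cli_main, [
            "features", "--in", str(sess), "--out", str(out), "--windows", "300",
        ])
        assert r.exit_code == 0, r.output
        assert (out / "features.tsv").exists()
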