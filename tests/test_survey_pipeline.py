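"""End-to-end survey orchestration, percentages, CLI."""

import os

import numpy as np
import pandas as pd
import pytest
import yaml

from mitosurvey import synthetic_data as sd
from mitosurvey.survey_pipeline import (
    PipelineError,
    SurveyConfig,
    category_percentages,
    load_config,
    run_survey,
)


@pytest.fixture(scope="module")
def survey_config(tmp_path_factory):
    bundle = sd.generate_bundle(sd.small_simulation_spec(seed=5))
    d = tmp_path_factory.mktemp("survey")
    paths = sd.write_bundle(bundle, d / "bundle")
    return SurveyConfig(
        alignment=paths["alignment"],
        metadata=paths["metadata"],
        genes=paths["genes"],
        effects=paths["effects"],
        pathogenic=paths["pathogenic"],
        out_dir=str(d / "out"),
        seed=9,
        n_reps=40,
        n_boot=30,
    )


@pytest.fixture(scope="module")
def report(survey_config):
    return run_survey(survey_config)


class TestCategoryPercentages:
    def test_structural_denominators(self):
        counts = {"synonymous": 2574, "nonsynonymous": 1263, "fourfold": 1177,
                  "nonsyn_benign": 922}
        pct = category_percentages(counts)
        assert round(pct["synonymous"], 1) == 67.1
        assert round(pct["nonsynonymous"], 1) == 32.9
        assert round(pct["fourfold"], 1) == 45.7
        assert round(pct["nonsyn_benign"], 1) == 73.0

    def test_zero_part(self):
        pct = category_percentages({"synonymous": 0, "nonsynonymous": 10})
        assert pct["synonymous"] == 0.0

    def test_zero_denominator_flagged(self):
        pct = category_percentages({"fourfold": 0, "synonymous": 0})
        assert np.isnan(pct["fourfold"])

    def test_groups_sum_to_hundred(self, report):
        t1 = report.table1.set_index("category")
        for col in ("pct_total", "pct_African", "pct_non-African"):
            s = t1.loc["synonymous", col] + t1.loc["nonsynonymous", col]
            assert abs(s - 100.0) <= 0.2
            effect = (t1.loc["nonsyn_benign", col] + t1.loc["nonsyn_damaging", col]
                      + t1.loc["nonsyn_unknown", col])
            assert abs(effect - 100.0) <= 0.2


class TestRunSurvey:
    def test_outputs_complete(self, report, survey_config):
        for df in (report.table1, report.table2, report.table3, report.table4,
                   report.ratios):
            assert len(df) > 0
        files = os.listdir(survey_config.out_dir)
        assert {
            "table1_sites.tsv", "table2_pi.tsv", "table3_maf.tsv",
            "table4_burden.tsv", "ratios.tsv", "variant_catalog.tsv", "run_log.txt",
        } <= set(files)
        log = open(os.path.join(survey_config.out_dir, "run_log.txt")).read()
        assert "config seed = 9" in log
        assert "site_count_definition" in log

    def test_deterministic_rerun_is_byte_identical(self, survey_config, report, tmp_path):
        snap = {
            f: open(os.path.join(survey_config.out_dir, f), "rb").read()
            for f in os.listdir(survey_config.out_dir)
        }
        run_survey(survey_config)
        for f, content in snap.items():
            assert open(os.path.join(survey_config.out_dir, f), "rb").read() == content, f

    def test_report_regeneration_from_catalog_dump(self, survey_config, report, tmp_path):
        """Reporting layer is idempotent: rebuilding the tables from the
        dumped variant catalogue equals the direct run."""
        cfg = SurveyConfig(**{**survey_config.__dict__,
                              "catalog_tsv": os.path.join(survey_config.out_dir,
                                                          "variant_catalog.tsv"),
                              "out_dir": None})
        rep2 = run_survey(cfg)
        for name in ("table1", "table3", "table4", "ratios"):
            pd.testing.assert_frame_equal(getattr(report, name), getattr(rep2, name))

    def test_monomorphic_bundle_reports_zero_sites(self, tmp_path):
        spec = sd.small_simulation_spec(seed=0)
        spec.categories = []
        paths = sd.write_bundle(sd.generate_bundle(spec), tmp_path / "b")
        cfg = SurveyConfig(alignment=paths["alignment"], metadata=paths["metadata"],
                           genes=paths["genes"], seed=0, n_reps=5, n_boot=5)
        rep = run_survey(cfg)
        assert rep.table1["sites_total"].sum() == 0
        assert rep.table4.filter(like="burden").to_numpy().sum() == 0

    def test_reader_error_names_the_stage(self, survey_config, tmp_path):
        cfg = SurveyConfig(**{**survey_config.__dict__,
                              "alignment": str(tmp_path / "missing.fa"),
                              "out_dir": None})
        with pytest.raises(PipelineError, match="read_alignment"):
            run_survey(cfg)

    def test_population_site_count_switch(self, survey_config):
        cfg = SurveyConfig(**{**survey_config.__dict__,
                              "site_count_definition": "population",
                              "out_dir": None})
        rep = run_survey(cfg)
        t = rep.table1.set_index("category")
        # per-population counts under re-calling can only shrink or match
        direct = run_survey(SurveyConfig(**{**survey_config.__dict__, "out_dir": None}))
        td = direct.table1.set_index("category")
        for pop in ("African", "non-African"):
            assert (t[f"sites_{pop}"] <= td[f"sites_{pop}"]).all()


class TestConfigAndCli:
    def test_yaml_config_round_trip(self, survey_config, tmp_path):
        p = tmp_path / "cfg.yaml"
        data = {k: v for k, v in survey_config.__dict__.items() if v is not None}
        p.write_text(yaml.safe_dump(data))
        cfg = load_config(p)
        assert cfg == SurveyConfig(**data)

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("alignment: x\nbogus_key: 1\n")
        with pytest.raises(Exception, match="bogus_key"):
            load_config(p)

    def test_cli_simulate_and_survey(self, tmp_path):
        from click.testing import CliRunner

        from mitosurvey.cli import main

        runner = CliRunner()
        bdir = str(tmp_path / "bundle")
        r = runner.invoke(main, ["simulate", "--small", "--seed", "4", "--out", bdir])
        assert r.exit_code == 0, r.output
        cfg = {
            "alignment": f"{bdir}/alignment.fasta",
            "metadata": f"{bdir}/samples.tsv",
            "genes": f"{bdir}/genes.gff3",
            "effects": f"{bdir}/effects.tsv",
            "pathogenic": f"{bdir}/pathogenic.tsv",
            "out_dir": str(tmp_path / "out"),
            "n_reps": 10,
            "n_boot": 10,
        }
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(cfg))
        r = runner.invoke(main, ["survey", "--config", str(p)])
        assert r.exit_code == 0, r.output
        assert os.path.exists(tmp_path / "out" / "table3_maf.tsv")
        r = runner.invoke(
            main,
            ["tables", "--catalog", str(tmp_path / "out" / "variant_catalog.tsv"),
             "--config", str(p), "--out", str(tmp_path / "out2")],
        )
        assert r.exit_code == 0, r.output
        assert os.path.exists(tmp_path / "out2" / "table4_burden.tsv")
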