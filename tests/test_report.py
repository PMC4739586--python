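"""Stepwise pipeline orchestration, league tables, and the CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import wardaudit as wa
from wardaudit.cli import main
from wardaudit.multilevel import MultilevelLogit
from wardaudit.report import StageError

from conftest import make_config, null_config


@pytest.fixture(scope="module")
def pipeline_report():
    """One stepwise run on a mixed-type mid-size world, reused across tests."""
    cfg = wa.SimulationConfig(
        n_hospitals={"municipal": 12, "provincial": 6, "regional": 3},
        wards_per_hospital_mean={"municipal": 4.0, "provincial": 9.0, "regional": 20.0},
        patients_per_ward_mean={"municipal": 40.0, "provincial": 45.0, "regional": 35.0},
        seed=77,
    )
    table, _ = wa.simulate_cohort(cfg)
    return table, wa.run_stepwise(table)


class TestRunStepwise:
    def test_structural_completeness(self, pipeline_report):
        """Four model blocks, 2 ICCs + 2 MORs + 2 PCVs + 4 POORs, 4+ AUCs."""
        _, rep = pipeline_report
        assert set(rep.fits) == {"model1", "model2", "model3", "model4"}
        assert set(rep.measures) == {"model3", "model4"}
        m4 = rep.measures["model4"]
        assert len(m4.pcv_by_level) == 2
        assert len(m4.poor_by_term) == 4
        for name in ("model1", "model2", "model3", "model4",
                     "model3_no_hospital", "model3_no_ward"):
            assert name in rep.auc
        assert "model3" in rep.auc_differences
        # the random levels appear only from model 3 onward
        assert not rep.fits["model2"].sigma2
        assert set(rep.fits["model3"].sigma2) == {"hospital", "ward"}

    def test_formatter_matches_fit_objects(self, pipeline_report):
        """Printed ORs are exp(beta) of the stored fits, no recomputation."""
        _, rep = pipeline_report
        table = rep.table_associations()
        for name, fit in rep.fits.items():
            ors = fit.odds_ratios()
            for term, row in ors.iterrows():
                assert table.loc[term, name].startswith(f"{row.OR:.2f} ")

    def test_variance_table_layout(self, pipeline_report):
        _, rep = pipeline_report
        tab = rep.table_variance()
        assert list(tab.columns) == ["model1", "model2", "model3", "model4"]
        assert tab.loc["auc"].notna().all()
        assert np.isnan(tab.loc["sigma2_ward", "model1"])
        assert tab.loc["pcv_ward", "model4"] == pytest.approx(
            round(rep.measures["model4"].pcv_by_level["ward"], 2)
        )

    def test_deterministic_rerun(self, pipeline_report):
        table, rep = pipeline_report
        again = wa.run_stepwise(table)
        a, b = json.loads(rep.to_json()), json.loads(again.to_json())
        for key in ("models", "auc", "measures", "risk_score"):
            assert a[key] == b[key]

    def test_null_world_pipeline(self):
        """No cluster variance, no contextual effects: ICCs ~ 0 and the
        random-effect AUC increment vanishes."""
        cfg = null_config(
            n_hospitals={"municipal": 12, "provincial": 6, "regional": 3},
            wards_per_hospital_mean={"municipal": 4.0, "provincial": 8.0, "regional": 16.0},
            patients_per_ward_mean={"municipal": 40.0, "provincial": 45.0, "regional": 35.0},
            seed=101,
        )
        table, _ = wa.simulate_cohort(cfg)
        rep = wa.run_stepwise(table)
        m3 = rep.measures["model3"]
        assert m3.icc_h < 0.01 and m3.icc_w < 0.01
        diff, _ = rep.auc_differences["model3"]
        assert abs(diff) < 0.01

    def test_stage_failure_names_stage(self, pipeline_report):
        table, _ = pipeline_report
        broken = wa.CohortTable(table.data.assign(death30=0))
        with pytest.raises(StageError, match="risk_score"):
            wa.run_stepwise(broken)


class TestLeagueTable:
    def test_null_world_intervals_mostly_cover_zero(self):
        cfg = null_config(seed=3)
        table, _ = wa.simulate_cohort(cfg)
        fit = wa.fit_three_level(table, ["age", "cm_cancer"])
        lt = wa.league_table(fit, "hospital")
        frac = (lt["flag"] == "indistinguishable").mean()
        assert frac >= 0.90
        assert sorted(lt["rank"]) == list(range(1, len(lt) + 1))

    def test_planted_outlier_ward_ranked_last(self):
        """A ward with +1.0 logit excess mortality lands at the bottom of
        the table with an interval excluding zero."""
        rng = np.random.default_rng(17)
        rows = []
        for h in range(10):
            for w in range(4):
                ward = f"h{h}_w{w}"
                bump = 1.0 if (h, w) == (0, 0) else 0.0
                n = 400
                p = 1.0 / (1.0 + np.exp(-(-2.2 + bump)))
                y = (rng.random(n) < p).astype(int)
                rows += [
                    {"death30": v, "ward_id": ward, "hospital_id": f"h{h}"} for v in y
                ]
        df = pd.DataFrame(rows)
        model = MultilevelLogit(
            df["death30"], np.ones((len(df), 1)), exog_names=["intercept"],
            ward=df["ward_id"], hospital=df["hospital_id"],
        )
        lt = wa.league_table(model.fit(), "ward")
        worst = lt.iloc[-1]
        assert worst["cluster"] == "h0_w0"
        assert worst["flag"] == "above"

    def test_tied_residuals_ordered_by_id(self, small_fit):
        res = small_fit.random_effects("ward")
        a, b = sorted(res.index[:2], reverse=True)  # deliberately unsorted
        fit = small_fit
        fit.ranef["ward"].loc[[a, b], "u"] = 0.123456
        lt = wa.league_table(fit, "ward")
        pos = lt.set_index("cluster")["rank"]
        assert abs(pos[a] - pos[b]) == 1
        assert pos[min(a, b)] < pos[max(a, b)]

    def test_absent_level_errors(self, pipeline_report):
        _, rep = pipeline_report
        with pytest.raises(KeyError):
            wa.league_table(rep.fits["model2"], "hospital")

    def test_caterpillar_plot_smoke(self, small_fit, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        lt = wa.league_table(small_fit, "hospital")
        ax = wa.plot_caterpillar(lt, title="hospitals")
        ax.figure.savefig(tmp_path / "caterpillar.png")


class TestCli:
    def test_simulate_filter_report_round_trip(self, tmp_path):
        runner = CliRunner()
        cfg = make_config(
            n_hospitals={"municipal": 12},
            wards_per_hospital_mean={"municipal": 3.0},
            patients_per_ward_mean={"municipal": 35.0},
            prior_hf_rate=0.25,
            nursing_home_rate=0.01,
            seed=7,
        )
        cfg_path = tmp_path / "sim.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg.to_dict()))

        raw_csv = tmp_path / "raw.csv"
        r = runner.invoke(main, [
            "simulate", "--config", str(cfg_path), "--raw",
            "--out", str(raw_csv), "--truth", str(tmp_path / "truth.json"),
        ])
        assert r.exit_code == 0, r.output

        cohort_csv = tmp_path / "cohort.csv"
        r = runner.invoke(main, [
            "filter", "--in", str(raw_csv), "--out", str(cohort_csv),
            "--min-hospital-size", "10",
            "--provenance", str(tmp_path / "flow.json"),
        ])
        assert r.exit_code == 0, r.output
        flow = json.loads((tmp_path / "flow.json").read_text())
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert flow["steps"][1]["removed"] == truth["exclusion_counts"]["prior_hf"]

        r = runner.invoke(main, [
            "riskscore", "--in", str(cohort_csv), "--out", str(tmp_path / "rs.json"),
        ])
        assert r.exit_code == 0, r.output
        assert "params" in json.loads((tmp_path / "rs.json").read_text())

        out_dir = tmp_path / "report"
        r = runner.invoke(main, [
            "report", "--in", str(cohort_csv), "--out-dir", str(out_dir),
        ])
        assert r.exit_code == 0, r.output
        for artefact in (
            "report.json", "table_associations.csv", "table_variance.csv",
            "league_hospital.csv", "league_ward.csv",
        ):
            assert (out_dir / artefact).exists()
        report = json.loads((out_dir / "report.json").read_text())
        assert set(report["models"]) == {"model1", "model2", "model3", "model4"}

    def test_fit_and_measures_commands(self, tmp_path):
        runner = CliRunner()
        cfg = make_config(
            n_hospitals={"municipal": 12},
            wards_per_hospital_mean={"municipal": 3.0},
            patients_per_ward_mean={"municipal": 35.0},
            seed=3,
        )
        table, _ = wa.simulate_cohort(cfg)
        cohort_csv = tmp_path / "cohort.csv"
        table.write(cohort_csv)
        for n in (3, 4):
            r = runner.invoke(main, [
                "fit", "--in", str(cohort_csv), "--model", str(n),
                "--out", str(tmp_path / f"fit{n}.json"),
            ])
            assert r.exit_code == 0, r.output
        r = runner.invoke(main, [
            "measures", "--fit3", str(tmp_path / "fit3.json"),
            "--fit4", str(tmp_path / "fit4.json"),
            "--out", str(tmp_path / "measures.json"),
        ])
        assert r.exit_code == 0, r.output
        payload = json.loads((tmp_path / "measures.json").read_text())
        assert set(payload["rounded"]["model4"]["poor_by_term"]) >= {
            "ward_volume_tertile[2]", "ward_volume_tertile[3]",
        }
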