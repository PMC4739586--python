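"""Multilevel logistic backends: closed forms, recovery, residuals, DIC."""

import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import wardaudit as wa
from wardaudit.multilevel import MultilevelLogit, split_rhat

from conftest import make_config, null_config


def _single_ward_frame(y, cols):
    df = pd.DataFrame({"death30": y, **cols})
    df["patient_id"] = [f"p{i}" for i in range(len(df))]
    df["age"] = df.get("age", 70)
    df["sex_eth"] = "swedish_female"
    df["ward_id"] = "w1"
    df["hospital_id"] = "h1"
    return df


class TestSingleLevel:
    def test_2x2_odds_ratio_exact(self):
        df = _single_ward_frame(
            [1] * 5 + [0] * 5 + [1] * 2 + [0] * 8, {"x": [1] * 10 + [0] * 10}
        )
        fit = wa.fit_single_level(df, ["x"])
        assert math.exp(fit.params["x"]) == pytest.approx(4.0, abs=1e-9)
        ors = fit.odds_ratios()
        assert ors.loc["x", "lo"] < 4.0 < ors.loc["x", "hi"]

    def test_intercept_only_is_logit_prevalence(self):
        y = [1] * 30 + [0] * 70
        fit = wa.fit_single_level(_single_ward_frame(y, {}), [])
        assert fit.params["intercept"] == pytest.approx(logit(0.3), abs=1e-8)

    def test_parameter_recovery_no_clusters(self):
        """Single-level world at n = 20,000: betas within 3 SE of truth."""
        rng = np.random.default_rng(14)
        n = 20_000
        age = rng.normal(71, 8, n)
        flag = rng.integers(0, 2, n)
        truth = {"age": 0.08, "flag": 0.6}
        y = (rng.random(n) < expit(-3 + 0.08 * (age - 71) + 0.6 * flag)).astype(int)
        df = _single_ward_frame(y, {"age": age - 71, "flag": flag})
        fit = wa.fit_single_level(df, ["age", "flag"])
        for name, b in truth.items():
            assert abs(fit.params[name] - b) < 3 * fit.bse[name]

    def test_rank_deficiency_names_column(self):
        df = _single_ward_frame([0, 1] * 10, {"x": [1, 0] * 10, "xx": [1, 0] * 10})
        with pytest.raises(wa.RankDeficientError, match="xx"):
            wa.fit_single_level(df, ["x", "xx"])


class TestThreeLevelLaplace:
    def test_zero_variance_world_boundary(self):
        """Generated with sigma2 = 0 at 100x4x50: both estimates < 0.02."""
        cfg = null_config(
            n_hospitals={"municipal": 100},
            wards_per_hospital_mean={"municipal": 4.0},
            patients_per_ward_mean={"municipal": 50.0},
            seed=23,
        )
        table, _ = wa.simulate_cohort(cfg)
        fit = wa.fit_three_level(table, ["age", "cm_cancer"])
        assert fit.sigma2["ward"].estimate < 0.02
        assert fit.sigma2["hospital"].estimate < 0.02

    def test_two_cluster_moment_oracle(self):
        """Two huge wards with a known log-odds gap: the ML variance tends
        to the method-of-moments value (mean squared deviation, ddof 0)."""
        rng = np.random.default_rng(77)
        n = 40_000
        p1, p2 = 0.08, 0.14
        y = np.concatenate([
            (rng.random(n) < p1).astype(float), (rng.random(n) < p2).astype(float)
        ])
        df = pd.DataFrame({
            "death30": y,
            "ward_id": ["w1"] * n + ["w2"] * n,
        })
        model = MultilevelLogit(
            df["death30"], np.ones((2 * n, 1)), exog_names=["intercept"],
            ward=df["ward_id"],
        )
        fit = model.fit()
        gap = logit(p2) - logit(p1)
        mom = (gap / 2) ** 2
        assert fit.sigma2["ward"].estimate == pytest.approx(mom, rel=0.15)

    def test_constrained_zero_matches_single_level(self, small_cohort):
        table, _ = small_cohort
        terms = ["age", "cm_cancer"]
        m = MultilevelLogit.from_dataframe(
            table.data, "death30", terms, ward="ward_id", hospital="hospital_id"
        )
        constrained = m.fit(sigma2_fixed={"ward": 0, "hospital": 0})
        single = wa.fit_single_level(table, terms)
        np.testing.assert_allclose(
            constrained.params, single.params, atol=1e-6
        )

    def test_agrees_with_lme4(self, tmp_path):
        """Independent oracle: lme4::glmer (Laplace) on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        cfg = make_config(
            n_hospitals={"municipal": 50},
            wards_per_hospital_mean={"municipal": 4.0},
            patients_per_ward_mean={"municipal": 40.0},
            sigma2_w=0.3, sigma2_h=0.1, seed=8,
        )
        table, _ = wa.simulate_cohort(cfg)
        df = table.data[["death30", "age", "cm_cancer", "ward_id", "hospital_id"]]
        df.to_csv(tmp_path / "cohort.csv", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{tmp_path / "cohort.csv"}")\n'
            'f <- glmer(death30 ~ age + cm_cancer + (1|hospital_id) + (1|ward_id),\n'
            '           data=d, family=binomial, nAGQ=0)\n'
            'f <- update(f, nAGQ=1)\n'
            'vc <- as.data.frame(VarCorr(f))\n'
            'out <- list(beta=as.list(fixef(f)),\n'
            '            s2=as.list(setNames(vc$vcov, vc$grp)))\n'
            'cat(jsonlite::toJSON(out, auto_unbox=TRUE))\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        ref = json.loads(proc.stdout)
        fit = wa.fit_three_level(df, ["age", "cm_cancer"])
        ours = {
            "(Intercept)": fit.params["intercept"],
            "age": fit.params["age"],
            "cm_cancer": fit.params["cm_cancer"],
        }
        for name, val in ref["beta"].items():
            assert ours[name] == pytest.approx(val, rel=0.05, abs=0.02)
        assert fit.sigma2["ward"].estimate == pytest.approx(
            ref["s2"]["ward_id"], rel=0.15
        )
        assert fit.sigma2["hospital"].estimate == pytest.approx(
            ref["s2"]["hospital_id"], rel=0.25, abs=0.01
        )


class TestShrunkenResiduals:
    def test_centering_and_shrinkage(self, small_cohort, small_fit):
        table, _ = small_cohort
        for level, col in (("ward", "ward_id"), ("hospital", "hospital_id")):
            res = small_fit.random_effects(level)
            assert abs(res["u"].mean()) < 0.05
            assert (res["lo"] <= res["u"]).all() and (res["u"] <= res["hi"]).all()
            np.testing.assert_allclose(res["hi"] - res["u"], 1.96 * res["se"])

    def test_on_target_cluster_near_zero_and_size_ladder(self):
        """Wards drawn at exactly the model rate: u ~ 0; under equal truth
        the smallest ward gets the widest interval."""
        rng = np.random.default_rng(55)
        sizes = [30, 120, 480, 1920]
        p = 0.10
        rows = []
        for j, n in enumerate(sizes):
            k = int(round(p * n))
            rows += [{"death30": 1, "ward_id": f"w{j}"}] * k
            rows += [{"death30": 0, "ward_id": f"w{j}"}] * (n - k)
        df = pd.DataFrame(rows)
        model = MultilevelLogit(
            df["death30"], np.ones((len(df), 1)), exog_names=["intercept"],
            ward=df["ward_id"],
        )
        fit = model.fit()
        res = fit.random_effects("ward").loc[[f"w{j}" for j in range(4)]]
        assert np.abs(res["u"]).max() < 0.05
        widths = (res["hi"] - res["lo"]).to_numpy()
        assert (np.diff(widths) < 0).all()  # monotone: bigger ward, tighter

    def test_shrinkage_toward_zero_vs_raw_deviation(self, small_cohort, small_fit):
        """|u_hat| never exceeds the raw cluster log-odds deviation."""
        table, _ = small_cohort
        df = table.data.copy()
        df["eta_fixed"] = small_fit.linear_predictor(include_levels=())
        res = small_fit.random_effects("hospital")
        grouped = df.groupby("hospital_id")
        for hosp, u in res["u"].items():
            sub = grouped.get_group(hosp)
            events = sub["death30"].sum()
            if events == 0 or events == len(sub):
                continue
            raw = logit(sub["death30"].mean()) - logit(expit(sub["eta_fixed"]).mean())
            assert abs(u) <= abs(raw) + 1e-8

    def test_absent_level_errors(self, small_fit):
        with pytest.raises(KeyError, match="region"):
            small_fit.random_effects("region")

    def test_comparative_se_option(self, small_fit):
        diag = small_fit.random_effects("ward", se="diagnostic")
        comp = small_fit.random_effects("ward", se="comparative")
        s2 = small_fit.sigma2["ward"].estimate
        np.testing.assert_allclose(
            diag["se"] ** 2 + comp["se"] ** 2, s2, atol=1e-8
        )


class TestMcmc:
    @pytest.fixture(scope="class")
    def mcmc_pair(self):
        """Laplace and MCMC fits of one moderately sized cohort."""
        cfg = make_config(
            n_hospitals={"municipal": 80},
            wards_per_hospital_mean={"municipal": 4.0},
            patients_per_ward_mean={"municipal": 60.0},
            seed=19,
        )
        table, _ = wa.simulate_cohort(cfg)
        terms = ["age", "sex_eth", "cm_cancer", "cm_respiratory"]
        model = MultilevelLogit.from_dataframe(
            table.data, "death30", terms,
            ward="ward_id", hospital="hospital_id",
            ref_levels={"sex_eth": "swedish_female"},
        )
        lap = model.fit()
        mc = model.fit_mcmc(
            n_iter=3000, burn=800, seed=4, start=lap, on_nonconvergence="warn"
        )
        return lap, mc

    def test_cross_method_or_agreement(self, mcmc_pair):
        """Laplace and MCMC odds ratios drift < 5% at n ~ 20,000."""
        lap, mc = mcmc_pair
        drift = np.abs(np.exp(mc.params - lap.params) - 1.0)
        assert float(drift.drop("intercept").max()) < 0.05

    def test_variance_credible_intervals(self, mcmc_pair):
        _, mc = mcmc_pair
        for level in ("ward", "hospital"):
            vc = mc.sigma2[level]
            assert vc.ci95[0] <= vc.estimate <= vc.ci95[1]
            assert vc.estimate >= 0

    def test_seed_determinism(self):
        cfg = make_config(
            n_hospitals={"municipal": 20},
            wards_per_hospital_mean={"municipal": 3.0},
            patients_per_ward_mean={"municipal": 30.0},
            seed=2,
        )
        table, _ = wa.simulate_cohort(cfg)
        model = MultilevelLogit.from_dataframe(
            table.data, "death30", ["age"], ward="ward_id", hospital="hospital_id"
        )
        fits = [
            model.fit_mcmc(n_iter=600, burn=200, seed=9, on_nonconvergence="warn")
            for _ in range(2)
        ]
        assert fits[0].dic == fits[1].dic
        pd.testing.assert_series_equal(fits[0].params, fits[1].params)

    def test_dic_unavailable_from_laplace(self, small_fit):
        with pytest.raises(wa.DicUnavailableError, match="aic"):
            small_fit.dic
        assert np.isfinite(small_fit.aic)

    def test_rhat_flags_nonconvergence(self):
        assert split_rhat(np.linspace(0, 1, 400)) > 1.05  # trending chain
        rng = np.random.default_rng(0)
        assert split_rhat(rng.normal(size=4000)) < 1.02


class TestDicModelComparison:
    @pytest.fixture(scope="class")
    def dic_triples(self):
        """DIC of (base, +noise, -true-covariate) over four seeded worlds."""
        out = []
        for seed in range(4):
            cfg = make_config(
                n_hospitals={"municipal": 25},
                wards_per_hospital_mean={"municipal": 3.0},
                patients_per_ward_mean={"municipal": 50.0},
                seed=seed,
            )
            table, _ = wa.simulate_cohort(cfg)
            df = table.data.copy()
            df["noise"] = np.random.default_rng(1000 + seed).integers(0, 2, len(df))

            def dic(terms):
                m = MultilevelLogit.from_dataframe(
                    df, "death30", terms, ward="ward_id", hospital="hospital_id"
                )
                fit = m.fit_mcmc(
                    n_iter=6000, burn=1200, seed=seed, on_nonconvergence="warn"
                )
                return fit.dic

            base = dic(["age", "cm_cancer"])
            out.append(
                (base, dic(["age", "cm_cancer", "noise"]), dic(["age"]))
            )
        return np.asarray(out)

    def test_noise_covariate_barely_moves_dic(self, dic_triples):
        assert abs(np.mean(dic_triples[:, 1] - dic_triples[:, 0])) < 2.0

    def test_true_covariate_lowers_dic(self, dic_triples):
        assert (dic_triples[:, 2] > dic_triples[:, 0]).all()
        assert np.mean(dic_triples[:, 2] - dic_triples[:, 0]) > 5.0
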