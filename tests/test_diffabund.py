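"""Moderated differential abundance: OLS limit, shrinkage, calls, contrasts."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import afproteome as afp
from afproteome.datatypes import AbundanceMatrix
from afproteome.diffabund import estimate_hyperparams, fit_protein_models


def _toy_two_group(effects, n_per_group=6, sd=0.3, seed=0, covariate=False):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.array(["midtrimester"] * n_per_group + ["term"] * n_per_group)
    Y = rng.normal(scale=sd, size=(n, len(effects)))
    Y += np.outer((group == "term").astype(float), np.asarray(effects))
    meta = pd.DataFrame(
        {
            "group": group,
            "gestational_age_weeks": np.r_[
                rng.uniform(17, 23, n_per_group), rng.uniform(37, 41, n_per_group)
            ],
            "fetal_sex": rng.choice(["F", "M"], size=n),
            "maternal_age_years": rng.normal(28, 5, size=n).round(1),
        },
        index=[f"S{i}" for i in range(n)],
    )
    matrix = AbundanceMatrix(
        pd.DataFrame(Y, index=meta.index,
                     columns=[f"A{i}" for i in range(len(effects))]),
        scale="log2",
    )
    return matrix, meta


class TestFit:
    def test_effect_is_group_mean_difference_without_covariates(self):
        Y = pd.DataFrame(
            {"A1": [8.0, 8.0, 8.0, 9.0, 9.0, 9.0]},
            index=[f"S{i}" for i in range(6)],
        )
        meta = pd.DataFrame(
            {
                "group": ["midtrimester"] * 3 + ["term"] * 3,
                "gestational_age_weeks": [18, 19, 20, 38, 39, 40],
                "fetal_sex": ["F"] * 6,
                "maternal_age_years": [30.0] * 6,
            },
            index=Y.index,
        )
        fit = fit_protein_models(
            AbundanceMatrix(Y, scale="log2"), meta, covariates=()
        )
        assert fit.table.loc["A1", "effect"] == pytest.approx(1.0)
        assert fit.df_resid == 4

    def test_collinear_covariate_rejected(self):
        matrix, meta = _toy_two_group([0.0])
        meta["dup"] = (meta["group"] == "term").astype(float)
        with pytest.raises(afp.ValidationError, match="rank deficient"):
            fit_protein_models(matrix, meta, covariates=("dup",))

    def test_estimates_unbiased_with_correct_spread(self, small_cfg):
        """Mean estimation error ~ 0 and its SD matches the OLS standard error."""
        errors = []
        for seed in range(30):
            cfg = small_cfg.replace(seed=100 + seed)
            m, meta, ann, truth = afp.simulate_cohort(cfg)
            norm, _ = afp.normalize_chain(
                m, ann, control_reference=truth.reference,
                calibrator_reference=truth.reference,
                plate_ids=meta.table["plate_id"], calibrators=truth.calibrators,
                steps=("hyb", "plate"), log2=True,
            )
            fit = fit_protein_models(
                norm.subset(analytes=ann.assay_ids), meta.table
            )
            de_ids = truth.de_analytes
            err = (
                fit.table.loc[de_ids, "effect"]
                - truth.analytes.loc[de_ids, "true_log2fc"]
            )
            scaled = err / (
                truth.analytes.loc[de_ids, "noise_sd"]
                * np.sqrt(fit.coef_unscaled_var)
            )
            errors.append(scaled.to_numpy())
        scaled = np.concatenate(errors)
        assert abs(scaled.mean()) < 3 / np.sqrt(len(scaled))
        assert abs(scaled.std() - 1.0) < 0.1


class TestModeration:
    def test_d0_zero_reduces_to_ols_t(self):
        matrix, meta = _toy_two_group(np.linspace(-1, 1, 40), seed=1)
        fit = fit_protein_models(matrix, meta, covariates=())
        _, mod = afp.moderate_empirical_bayes(
            fit, afp.EBHyperparams(d0=0.0, s0_sq=1.0)
        )
        se = np.sqrt(fit.coef_unscaled_var * fit.table["s2"])
        t_ols = fit.table["effect"] / se
        assert np.abs(mod["t"] - t_ols).max() < 1e-10
        assert (mod["df_total"] == fit.df_resid).all()

    def test_d0_infinite_pins_variance_at_prior(self):
        matrix, meta = _toy_two_group(np.zeros(30), seed=2)
        fit = fit_protein_models(matrix, meta, covariates=())
        _, mod = afp.moderate_empirical_bayes(
            fit, afp.EBHyperparams(d0=np.inf, s0_sq=0.04)
        )
        assert np.allclose(mod["s2_post"], 0.04)

    def test_hyperparameter_recovery(self):
        """(d0, s0^2) estimated within 15% from scaled-inv-chi-square draws."""
        d0_true, s0_true, d = 4.0, 0.25, 24
        rng = np.random.default_rng(3)
        d0_est, s0_est = [], []
        for _ in range(5):
            s2_true = s0_true * d0_true / rng.chisquare(d0_true, size=2000)
            s2_obs = s2_true * rng.chisquare(d, size=2000) / d
            hp = estimate_hyperparams(s2_obs, d)
            d0_est.append(hp.d0)
            s0_est.append(hp.s0_sq)
        assert abs(np.mean(d0_est) - d0_true) / d0_true < 0.15
        assert abs(np.mean(s0_est) - s0_true) / s0_true < 0.15

    def test_too_few_analytes_rejected(self):
        with pytest.raises(afp.ValidationError, match=">= 10 analytes"):
            estimate_hyperparams(np.full(5, 0.2), 10)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: R limma on the same toy data, t and p to 1e-8."""
        rng = np.random.default_rng(42)
        n, p = 14, 60
        group = np.array([0.0] * 7 + [1.0] * 7)
        sd = np.sqrt(0.25 * 4 / rng.chisquare(4, size=p))
        Y = rng.normal(size=(n, p)) * sd + np.outer(group, rng.normal(0, 1, p))
        cov = rng.normal(size=n)
        pd.DataFrame(Y).to_csv(tmp_path / "Y.tsv", sep="\t", index=False)
        pd.DataFrame({"intercept": 1.0, "group": group, "cov": cov}).to_csv(
            tmp_path / "design.tsv", sep="\t", index=False
        )
        rscript = """
        suppressMessages(library(limma))
        Y <- as.matrix(read.delim("Y.tsv")); design <- as.matrix(read.delim("design.tsv"))
        fit <- eBayes(lmFit(t(Y), design))
        write.table(data.frame(t=fit$t[,"group"], p=fit$p.value[,"group"],
                               d0=fit$df.prior, s0=fit$s2.prior),
                    "out.tsv", sep="\t", row.names=FALSE, quote=FALSE)
        """
        (tmp_path / "check.R").write_text(rscript)
        subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")

        meta = pd.DataFrame(
            {"grp": np.where(group == 1, "b", "a"), "cov": cov},
            index=[f"S{i}" for i in range(n)],
        )
        matrix = AbundanceMatrix(
            pd.DataFrame(Y, index=meta.index, columns=[f"A{i}" for i in range(p)]),
            scale="log2",
        )
        fit = fit_protein_models(
            matrix, meta, covariates=("cov",), group_col="grp", contrast=("b", "a")
        )
        hp, mod = afp.moderate_empirical_bayes(fit)
        assert hp.d0 == pytest.approx(ref["d0"][0], rel=1e-5)
        assert hp.s0_sq == pytest.approx(ref["s0"][0], rel=1e-5)
        assert np.abs(mod["t"].to_numpy() - ref["t"].to_numpy()).max() < 1e-8
        assert np.abs(mod["p"].to_numpy() - ref["p"].to_numpy()).max() < 1e-8


class TestBH:
    def test_hand_computed_step_up(self):
        q = afp.bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert afp.bh_adjust([0.37])[0] == pytest.approx(0.37)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, pvals):
        p = np.asarray(pvals)
        q = afp.bh_adjust(p)
        assert ((q >= p - 1e-12) | np.isclose(q, p)).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_uniform_null_yields_almost_no_discoveries(self):
        rng = np.random.default_rng(4)
        fracs = [
            (afp.bh_adjust(rng.uniform(size=1310)) < 0.1).mean()
            for _ in range(100)
        ]
        assert np.mean(fracs) <= 0.001

    def test_out_of_range_rejected(self):
        with pytest.raises(afp.ValidationError):
            afp.bh_adjust([0.2, 1.4])


class TestCallsAndContrasts:
    def test_call_rule_boundaries(self):
        table = pd.DataFrame(
            {"log2_fc": [0.58, -0.60], "q": [0.01, 0.05]},
            index=["A1", "A2"],
        )
        called, n_up, n_down = afp.call_significant(table)
        assert not called.loc["A1", "significant"]  # FC 1.494 < 1.5
        assert called.loc["A2", "significant"]
        assert called.loc["A2", "direction"] == "down"
        assert (n_up, n_down) == (0, 1)

    def test_swapping_groups_negates_effects_and_keeps_p(self):
        matrix, meta = _toy_two_group(np.linspace(-1, 1, 25), seed=5)
        a = afp.run_differential_abundance(matrix, meta, covariates=())
        b = afp.run_differential_abundance(
            matrix, meta, covariates=(), contrast=("midtrimester", "term")
        )
        assert np.allclose(a["log2_fc"], -b["log2_fc"])
        assert np.allclose(a["p"], b["p"])

    def test_compare_adjustments_identity_and_flip(self):
        matrix, meta = _toy_two_group(np.r_[np.full(5, 1.2), np.zeros(20)], seed=6)
        de = afp.run_differential_abundance(matrix, meta, covariates=())
        assert de["significant"].any()
        r, agree = afp.compare_adjustments(de, de)
        assert (r, agree) == (pytest.approx(1.0), 1.0)
        flipped = de.copy()
        flipped["log2_fc"] = -flipped["log2_fc"]
        _, agree = afp.compare_adjustments(de, flipped)
        assert agree == 0.0

    def test_bmi_adjustment_is_insensitive_when_bmi_effect_weak(self, small_cfg):
        """With a weak planted BMI effect, fold changes with and without the
        BMI covariate correlate > 0.99 over the called analytes."""
        cfg = small_cfg.replace(bmi_slope_sd=0.01, seed=21)
        m, meta, ann, truth = afp.simulate_cohort(cfg)
        norm, _ = afp.normalize_chain(
            m, ann, control_reference=truth.reference,
            calibrator_reference=truth.reference,
            plate_ids=meta.table["plate_id"], calibrators=truth.calibrators,
            steps=("hyb", "plate"), log2=True,
        )
        assay = norm.subset(analytes=ann.assay_ids)
        base = afp.run_differential_abundance(assay, meta)
        with_bmi = afp.run_differential_abundance(
            assay, meta,
            covariates=("fetal_sex", "maternal_age_years", "bmi_kg_m2"),
        )
        r, agree = afp.compare_adjustments(base, with_bmi)
        assert r > 0.99
        assert agree == 1.0

    def test_midtrimester_split_boundaries(self):
        meta = pd.DataFrame(
            {
                "group": ["midtrimester"] * 4,
                "gestational_age_weeks": [16.4, 21.0, 21.1, 24.0],
                "fetal_sex": ["F"] * 4,
                "maternal_age_years": [30.0] * 4,
            },
            index=["S1", "S2", "S3", "S4"],
        )
        early, late = afp.split_midtrimester(meta)
        assert list(early.index) == ["S1", "S2"]  # 21.0 weeks is early
        assert list(late.index) == ["S3", "S4"]  # 21.1 weeks is late

    def test_split_requires_both_subgroups(self):
        meta = pd.DataFrame(
            {
                "group": ["midtrimester"] * 2,
                "gestational_age_weeks": [17.0, 18.0],
                "fetal_sex": ["F", "M"],
                "maternal_age_years": [30.0, 31.0],
            },
            index=["S1", "S2"],
        )
        with pytest.raises(afp.ValidationError, match="late"):
            afp.split_midtrimester(meta)
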