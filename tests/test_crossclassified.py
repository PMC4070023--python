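"""REML engine: ANOVA and lme4 oracles, BLUP shrinkage, ICCs, diagnostics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from schoolva.crossclassified import (ModelError, ModelSpec, NotConvergedError,
                                      RankDeficientError, fit_reml, icc,
                                      raw_school_residuals, school_blups)


def one_way_frame(k, m, var_u, var_e, seed):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(var_u), k)
    y = np.repeat(u, m) + rng.normal(0, np.sqrt(var_e), k * m)
    return pd.DataFrame({
        "bmi_sds": y,
        "school_id": np.repeat([f"S{i:03d}" for i in range(k)], m)}), y


def anova_estimates(y, k, m):
    gm = y.reshape(k, m).mean(axis=1)
    msb = m * np.sum((gm - gm.mean()) ** 2) / (k - 1)
    msw = np.sum((y.reshape(k, m) - gm[:, None]) ** 2) / (k * (m - 1))
    return (msb - msw) / m, msw


class TestRemlOracles:
    @pytest.mark.parametrize("k, m, var_u, seed", [
        (25, 12, 0.16, 1), (10, 30, 0.5, 2), (40, 5, 0.05, 3)])
    def test_balanced_one_way_matches_anova(self, k, m, var_u, seed):
        df, y = one_way_frame(k, m, var_u, 1.0, seed)
        fit = fit_reml(df, ModelSpec(adjusted=False, include_neighbourhood=False))
        vu, ve = anova_estimates(y, k, m)
        assert fit.converged
        assert fit.components.var_school == pytest.approx(vu, abs=1e-8)
        assert fit.components.var_residual == pytest.approx(ve, abs=1e-8)

    def test_zero_between_variance_pinned_at_boundary(self):
        # identical within-school patterns: between-school MS is exactly 0
        pattern = np.arange(8.0) - 3.5
        df = pd.DataFrame({
            "bmi_sds": np.tile(pattern, 10),
            "school_id": np.repeat([f"S{i}" for i in range(10)], 8)})
        fit = fit_reml(df, ModelSpec(adjusted=False, include_neighbourhood=False))
        assert fit.components.var_school <= 1e-6
        assert np.abs(school_blups(fit)["residual"]).max() == 0.0

    def test_crossed_fit_matches_lme4(self, tmp_path):
        rng = np.random.default_rng(42)
        n, ns, nl = 1200, 25, 40
        school = rng.integers(0, ns, n)
        lsoa = rng.integers(0, nl, n)
        u = rng.normal(0, 0.2, ns)
        v = rng.normal(0, 0.12, nl)
        y = 0.3 + u[school] + v[lsoa] + rng.normal(0, 1, n)
        df = pd.DataFrame({"bmi_sds": y,
                           "school_id": [f"S{i:03d}" for i in school],
                           "lsoa_id": [f"L{i:03d}" for i in lsoa]})
        csv = tmp_path / "xc.csv"
        df.to_csv(csv, index=False)
        fit = fit_reml(df, ModelSpec(adjusted=False))

        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH"
        script = tmp_path / "oracle.R"
        blup_csv = tmp_path / "blups.csv"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- lmer(bmi_sds ~ 1 + (1|school_id) + (1|lsoa_id), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(m))
for (i in 1:nrow(vc)) cat(vc$grp[i], format(vc$vcov[i], digits=12), "\\n")
cat("REMLcrit", format(REMLcrit(m), digits=12), "\\n")
r <- ranef(m)$school_id
write.csv(data.frame(level=rownames(r), blup=r[,1]), "{blup_csv}",
          row.names=FALSE)
""")
        out = subprocess.run([rscript, str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = {}
        for line in out.stdout.splitlines():
            parts = line.split()
            if len(parts) == 2:
                ref[parts[0]] = float(parts[1])
        assert fit.components.var_school == pytest.approx(
            ref["school_id"], rel=2e-3)
        assert fit.components.var_neighbourhood == pytest.approx(
            ref["lsoa_id"], rel=2e-3)
        assert fit.components.var_residual == pytest.approx(
            ref["Residual"], rel=1e-4)
        assert -2 * fit.reml_loglik == pytest.approx(ref["REMLcrit"], abs=1e-2)
        blups_r = pd.read_csv(blup_csv).set_index("level")["blup"]
        blups_py = school_blups(fit)["residual"]
        assert np.abs(blups_py - blups_r.reindex(blups_py.index)).max() < 1e-4


class TestBlups:
    def test_shrinkage_closed_form(self):
        df, y = one_way_frame(15, 20, 0.3, 1.0, seed=9)
        fit = fit_reml(df, ModelSpec(adjusted=False, include_neighbourhood=False))
        gam = fit.components.var_school / fit.components.var_residual
        shrink = 20 * gam / (1 + 20 * gam)
        beta0 = fit.beta.loc["const", "estimate"]
        gm = y.reshape(15, 20).mean(axis=1)
        hand = shrink * (gm - beta0)
        got = school_blups(fit)["residual"].to_numpy()
        assert np.max(np.abs(got - hand)) < 1e-8

    def test_blups_sum_to_zero_with_intercept(self, small_panel):
        sub = small_panel[small_panel["year"] == "2006/07"]
        fit = fit_reml(sub, ModelSpec())
        assert abs(school_blups(fit)["residual"].sum()) < 1e-6

    def test_shrinkage_reduces_dispersion(self, small_panel):
        sub = small_panel[small_panel["year"] == "2006/07"]
        fit = fit_reml(sub, ModelSpec())
        raw = raw_school_residuals(sub, fit)
        assert school_blups(fit)["residual"].var() <= raw.var()

    def test_prediction_se_shrinks_with_school_size(self, small_panel):
        sub = small_panel[small_panel["year"] == "2006/07"]
        fit = fit_reml(sub, ModelSpec())
        b = school_blups(fit)
        if fit.components.var_school > 0:
            rho = pd.Series(b["se"]).corr(pd.Series(b["n_pupils"]),
                                          method="spearman")
            assert rho < -0.3

    def test_non_converged_fit_refused(self, small_panel):
        sub = small_panel[small_panel["year"] == "2006/07"]
        fit = fit_reml(sub, ModelSpec())
        fit.converged = False
        with pytest.raises(NotConvergedError):
            school_blups(fit)


class TestIcc:
    def test_arithmetic_from_components(self, small_panel):
        sub = small_panel[small_panel["year"] == "2006/07"]
        fit = fit_reml(sub, ModelSpec(adjusted=False))
        comp = fit.components
        out = icc(fit)
        assert out["school"] == pytest.approx(comp.var_school / comp.total)
        assert out["neighbourhood"] == pytest.approx(
            comp.var_neighbourhood / comp.total)
        assert 0 <= out["school"] < 1

    def test_refused_on_adjusted_model(self, small_panel):
        sub = small_panel[small_panel["year"] == "2006/07"]
        fit = fit_reml(sub, ModelSpec(adjusted=True))
        with pytest.raises(ModelError):
            icc(fit)


class TestDiagnostics:
    def test_rank_deficient_design_names_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "bmi_sds": rng.normal(size=100),
            "school_id": np.repeat([f"S{i}" for i in range(10)], 10),
            "lsoa_id": np.tile([f"L{i}" for i in range(10)], 10),
            "ethnicity": "White-British",
            "imd_norm": 0.25,  # constant: aliased with the intercept
        })
        with pytest.raises(RankDeficientError, match="imd_norm"):
            fit_reml(df, ModelSpec(adjusted=True))

    def test_objective_never_increases(self, small_panel):
        sub = small_panel[small_panel["year"] == "2006/07"]
        fit = fit_reml(sub, ModelSpec())
        path = np.asarray(fit.objective_path)
        assert np.all(np.diff(path) <= 1e-9)

    def test_missing_rows_dropped_and_counted(self, small_panel):
        sub = small_panel[small_panel["year"] == "2006/07"].copy()
        sub.iloc[:7, sub.columns.get_loc("imd_norm")] = np.nan
        fit = fit_reml(sub, ModelSpec())
        assert fit.n_dropped == 7
        assert fit.n_obs == len(sub) - 7

    def test_neighbourhood_factor_changes_ranks_little(self, small_panel):
        sub = small_panel[small_panel["year"] == "2007/08"]
        with_nb = school_blups(fit_reml(sub, ModelSpec()))
        without = school_blups(fit_reml(
            sub, ModelSpec(include_neighbourhood=False)))
        rho = with_nb["residual"].corr(without["residual"], method="spearman")
        assert rho > 0.9
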