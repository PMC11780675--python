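"""The REML engine against closed-form and external oracles."""

import numpy as np
import pandas as pd
import pytest

from potatovc.reml import (
    ConvergenceError,
    RandomTerm,
    ReMLError,
    VarianceModelSpec,
    _MMEProblem,
    adjusted_entry_means,
    fit_reml,
    lrt,
    pairwise_difference_variance,
)

from conftest import anova_one_way, one_way

ONE_WAY_SPEC = VarianceModelSpec("y", ("1",), (RandomTerm("group", "grp"),))


class TestAgainstOracles:
    def test_balanced_one_way_matches_anova(self):
        """On balanced one-way data REML equals the ANOVA estimators."""
        df = one_way(n_groups=50, reps=4, sg2=2.0, se2=1.0, seed=3)
        fit = fit_reml(df, ONE_WAY_SPEC)
        sg_hat, se_hat = anova_one_way(df)
        assert fit.varcomp["group"] == pytest.approx(sg_hat, abs=1e-6)
        assert fit.resid == pytest.approx(se_hat, abs=1e-6)

    def test_balanced_two_way_matches_anova(self):
        """Balanced crossed two-way random model equals its ANOVA solution."""
        rng = np.random.default_rng(7)
        a_levels, b_levels, reps = 12, 10, 3
        sa2, sb2, se2 = 1.5, 0.8, 1.0
        a = rng.normal(0, np.sqrt(sa2), a_levels)
        b = rng.normal(0, np.sqrt(sb2), b_levels)
        rows = []
        for i in range(a_levels):
            for j in range(b_levels):
                for _ in range(reps):
                    rows.append((f"a{i}", f"b{j}",
                                 a[i] + b[j] + rng.normal(0, np.sqrt(se2))))
        df = pd.DataFrame(rows, columns=["A", "B", "y"])
        spec = VarianceModelSpec(
            "y", ("1",), (RandomTerm("A", "A"), RandomTerm("B", "B"))
        )
        fit = fit_reml(df, spec)
        # ANOVA estimators for the additive two-way random model
        ga = df.groupby("A")["y"].mean()
        gb = df.groupby("B")["y"].mean()
        pred = df["A"].map(ga) + df["B"].map(gb) - df["y"].mean()
        sse = ((df["y"] - pred) ** 2).sum()
        mse = sse / (len(df) - a_levels - b_levels + 1)
        msa = b_levels * reps * ga.var(ddof=1)
        msb = a_levels * reps * gb.var(ddof=1)
        assert fit.resid == pytest.approx(mse, abs=1e-6)
        assert fit.varcomp["A"] == pytest.approx(
            (msa - mse) / (b_levels * reps), abs=1e-6)
        assert fit.varcomp["B"] == pytest.approx(
            (msb - mse) / (a_levels * reps), abs=1e-6)

    def test_against_statsmodels_mixedlm(self):
        """Independent cross-check against statsmodels' REML fit."""
        statsmodels = pytest.importorskip("statsmodels.api")
        df = one_way(n_groups=30, reps=3, sg2=1.2, se2=0.7, seed=11)
        fit = fit_reml(df, ONE_WAY_SPEC)
        md = statsmodels.MixedLM.from_formula("y ~ 1", groups="grp", data=df)
        ml = md.fit(reml=True)
        assert fit.varcomp["group"] == pytest.approx(
            float(ml.cov_re.iloc[0, 0]), rel=1e-4)
        assert fit.resid == pytest.approx(float(ml.scale), rel=1e-4)

    def test_unbalanced_aems_match_gls_oracle(self, simulated_small):
        """AEMs equal explicit dense GLS at the estimated variances."""
        df = simulated_small.iloc[:400].reset_index(drop=True)
        spec = VarianceModelSpec(
            "T", ("1", "C(clone_id)"),
            (RandomTerm("environment", "environment_id"),
             RandomTerm("block", "block_id")),
        )
        fit = fit_reml(df, spec)
        pr = fit._problem
        X = pr.X
        V = np.eye(pr.n) * fit.resid
        for tm in pr.terms:
            Z = pr.Z[:, tm.start: tm.start + tm.levels.size].toarray()
            V += fit.varcomp[tm.term.name] * Z @ Z.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ pr.y)
        aem = adjusted_entry_means(fit, "clone_id")
        labels = dict(zip(pr.fixed_names, beta))
        mu = labels["(Intercept)"]
        for clone, val in aem.items():
            expect = mu + labels.get(f"clone_id[{clone}]", 0.0)
            assert val == pytest.approx(expect, abs=1e-5)


class TestInvariances:
    def test_duplicating_records_keeps_variance_ratios(self):
        """Doubling every record leaves variance-ratio estimates nearly
        unchanged once replication is high (the residual degrees of
        freedom shift by O(1/r), which the ANOVA oracle confirms)."""
        df = one_way(n_groups=40, reps=40, seed=5)
        fit1 = fit_reml(df, ONE_WAY_SPEC)
        fit2 = fit_reml(pd.concat([df, df], ignore_index=True), ONE_WAY_SPEC)
        r1 = fit1.varcomp["group"] / fit1.resid
        r2 = fit2.varcomp["group"] / fit2.resid
        assert r2 == pytest.approx(r1, rel=0.05)

    def test_redundant_fixed_column_leaves_loglik_unchanged(self):
        """A linearly dependent fixed column is dropped, not fitted."""
        df = one_way(n_groups=30, reps=3, seed=9)
        df["x1"] = np.tile([0.0, 1.0, 2.0], 30)
        df["x2"] = 2.0 * df["x1"]  # redundant
        f_base = fit_reml(df, VarianceModelSpec(
            "y", ("1", "x1"), (RandomTerm("group", "grp"),)))
        f_red = fit_reml(df, VarianceModelSpec(
            "y", ("1", "x1", "x2"), (RandomTerm("group", "grp"),)))
        assert f_red.dropped_fixed
        assert f_red.loglik == pytest.approx(f_base.loglik, abs=1e-6)

    def test_constrained_heterogeneous_residual_equals_pooled(self):
        """Het-residual likelihood at equal group values = pooled fit."""
        df = one_way(n_groups=30, reps=4, seed=13)
        df["env"] = np.where(np.arange(len(df)) % 2 == 0, "E1", "E2")
        pooled = fit_reml(df, ONE_WAY_SPEC)
        het_spec = VarianceModelSpec(
            "y", ("1",), (RandomTerm("group", "grp"),), residual_by="env"
        )
        pr = _MMEProblem(df, het_spec)
        theta = np.log(np.array(
            [pooled.varcomp["group"], pooled.resid, pooled.resid]
        ))
        neg2, _, _ = pr.evaluate(theta)
        assert -0.5 * neg2 == pytest.approx(pooled.loglik, abs=1e-6)

    def test_zero_signal_group_variance_hits_boundary(self):
        """With no between-group signal the median sigma_g^2 estimate is
        essentially zero and boundary collapse is the typical outcome."""
        ests = []
        hits = 0
        for seed in range(30):
            df = one_way(n_groups=30, reps=4, sg2=0.0, se2=1.0, seed=seed)
            fit = fit_reml(df, ONE_WAY_SPEC)
            ests.append(fit.varcomp["group"] / fit.resid)
            if fit.varcomp["group"] == 0.0 and ("group", "") in fit.boundary:
                hits += 1
        assert np.median(ests) < 0.05
        assert hits >= 10

    def test_tied_terms_share_one_variance(self):
        """Terms tied together are estimated with a single parameter."""
        rng = np.random.default_rng(21)
        n = 400
        g1 = rng.integers(0, 20, n)
        g2 = rng.integers(0, 20, n)
        y = (rng.normal(0, 1.0, 20)[g1] + rng.normal(0, 1.0, 20)[g2]
             + rng.normal(0, 1.0, n))
        df = pd.DataFrame({
            "y": y, "f1": [f"a{i}" for i in g1], "f2": [f"b{i}" for i in g2]
        })
        fit = fit_reml(df, VarianceModelSpec(
            "y", ("1",),
            (RandomTerm("t1", "f1", tie="shared"),
             RandomTerm("t2", "f2", tie="shared")),
        ))
        assert fit.varcomp["t1"] == fit.varcomp["t2"]


class TestAdjustedMeans:
    def test_single_environment_aem_is_arithmetic_mean(self):
        """Balanced complete data: AEM = clone mean."""
        rng = np.random.default_rng(2)
        clones = [f"c{i}" for i in range(6)]
        rows = [(c, rng.normal(5.0, 1.0)) for c in clones for _ in range(4)]
        df = pd.DataFrame(rows, columns=["clone_id", "y"])
        df["env"] = "E1"
        spec = VarianceModelSpec(
            "y", ("1", "C(clone_id)"), (RandomTerm("environment", "env"),)
        )
        fit = fit_reml(df, spec)
        aem = adjusted_entry_means(fit, "clone_id")
        means = df.groupby("clone_id")["y"].mean()
        for c in clones:
            assert aem[c] == pytest.approx(means[c], abs=1e-6)

    def test_translation_equivariance(self, simulated_small):
        """Adding a constant shifts every AEM by that constant."""
        df = simulated_small.iloc[:300].reset_index(drop=True)
        spec = VarianceModelSpec(
            "T", ("1", "C(clone_id)"),
            (RandomTerm("block", "block_id"),),
        )
        f0 = fit_reml(df, spec)
        df2 = df.copy()
        df2["T"] = df2["T"] + 7.5
        f1 = fit_reml(df2, spec)
        a0 = adjusted_entry_means(f0, "clone_id")
        a1 = adjusted_entry_means(f1, "clone_id")
        assert np.allclose(a1 - a0, 7.5, atol=1e-4)


class TestPairwiseDifferenceVariance:
    def test_iid_entries_closed_form(self):
        """Equal replication r, residual only: nu = 2 sigma^2 / r."""
        rng = np.random.default_rng(4)
        clones = [f"c{i}" for i in range(20)]
        r = 5
        rows = [(c, rng.normal(0, 1)) for c in clones for _ in range(r)]
        df = pd.DataFrame(rows, columns=["clone_id", "y"])
        spec = VarianceModelSpec("y", ("1", "C(clone_id)"), ())
        fit = fit_reml(df, spec)
        nu = pairwise_difference_variance(fit, "clone_id", entries=clones)
        assert nu == pytest.approx(2 * fit.resid / r, rel=1e-6)

    def test_sampled_agrees_with_exhaustive(self, simulated_small):
        df = simulated_small
        spec = VarianceModelSpec(
            "T", ("1", "C(clone_id)"),
            (RandomTerm("environment", "environment_id"),
             RandomTerm("block", "block_id")),
        )
        fit = fit_reml(df, spec)
        entries = sorted(df.loc[df["is_entry"] == 1, "clone_id"].unique())
        nu_ex = pairwise_difference_variance(fit, entries=entries)
        nu_s = pairwise_difference_variance(
            fit, entries=entries, max_exhaustive=10, n_sample=100_000, seed=1
        )
        assert nu_s == pytest.approx(nu_ex, rel=0.01)

    def test_fewer_than_two_entries_raises(self):
        df = one_way()
        df["clone_id"] = "only"
        spec = VarianceModelSpec(
            "y", ("1", "C(grp)"), (RandomTerm("c", "clone_id"),)
        )
        fit = fit_reml(df, spec)
        with pytest.raises(ReMLError):
            pairwise_difference_variance(fit, "grp", entries=["g000"])


class TestLrt:
    def test_equal_logliks_give_zero_statistic(self):
        df = one_way(seed=1)
        fit = fit_reml(df, ONE_WAY_SPEC)
        stat, p = lrt(fit, fit, df=1)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_reference_quantile(self):
        """Statistic 3.841 on 1 df sits at p = 0.050."""
        df = one_way(seed=1)
        fit = fit_reml(df, ONE_WAY_SPEC)
        red = fit_reml(df, VarianceModelSpec(
            "y", ("1",), (RandomTerm("group", "grp"),)))
        # synthesise the printed quantile through the public helper
        red.loglik = fit.loglik - 3.841 / 2.0
        stat, p = lrt(fit, red, df=1)
        assert stat == pytest.approx(3.841)
        assert p == pytest.approx(0.050, abs=5e-4)

    def test_mismatched_fixed_effects_rejected(self):
        df = one_way(seed=1)
        df["x"] = np.arange(len(df), dtype=float)
        full = fit_reml(df, VarianceModelSpec(
            "y", ("1", "x"), (RandomTerm("group", "grp"),)))
        red = fit_reml(df, ONE_WAY_SPEC)
        with pytest.raises(ReMLError):
            lrt(full, red, df=1)


class TestValidation:
    def test_missing_factor_column_raises(self):
        df = one_way()
        with pytest.raises(ReMLError):
            fit_reml(df, VarianceModelSpec(
                "y", ("1",), (RandomTerm("bad", "nope"),)))

    def test_missing_response_raises(self):
        df = one_way()
        with pytest.raises(ReMLError):
            fit_reml(df, VarianceModelSpec(
                "z", ("1",), (RandomTerm("group", "grp"),)))

    def test_all_missing_response_raises(self):
        df = one_way()
        df["y"] = np.nan
        with pytest.raises(ReMLError):
            fit_reml(df, ONE_WAY_SPEC)
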