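"""Heritabilities, market segments and the population decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from potatovc import ladder
from potatovc.reml import ReMLError, _MMEProblem, fit_reml
from potatovc.scenario import FamilySpec, SyntheticScenario, TraitSpec
from potatovc.synthetic import generate_design, simulate_trait


class TestHeritabilityFormulas:
    @pytest.mark.parametrize("sg2,nu,expected", [
        (1.0, 0.0, 1.0),
        (1.0, 1.0, 0.5),
    ])
    def test_entry_mean_examples(self, sg2, nu, expected):
        assert ladder.heritability_entry_mean(sg2, nu) == expected

    def test_halved_nu_variant(self):
        assert ladder.heritability_entry_mean(1.0, 1.0, halve_nu=True) \
            == pytest.approx(2 / 3)

    def test_plot_basis_zero_genetic_variance(self):
        assert ladder.heritability_plot(0.0, 0.5) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            ladder.heritability_entry_mean(0.0, 0.0)
        with pytest.raises(ValueError):
            ladder.heritability_plot(0.0, 0.0)

    def test_bounds_and_monotonicity(self):
        """h2 in [0,1], increasing in sigma_g2, decreasing in nu/eps."""
        grid = np.linspace(0.01, 3.0, 7)
        for f in (ladder.heritability_entry_mean, ladder.heritability_plot):
            vals_g = [f(g, 1.0) for g in grid]
            vals_n = [f(1.0, n) for n in grid]
            assert all(0 <= v <= 1 for v in vals_g + vals_n)
            assert np.all(np.diff(vals_g) > 0)
            assert np.all(np.diff(vals_n) < 0)

    def test_simulation_recovery(self, recovery_design, small_trait):
        """h2_plot near the generating ratio on synthetic data."""
        res = []
        for seed in range(5):
            sim = simulate_trait(recovery_design, small_trait,
                                 seed=3000 + seed, standardize_effects=True)
            h = ladder.compute_heritabilities(sim, "T")
            res.append(h.h2_plot)
        truth = small_trait.sigma_g2 / (small_trait.sigma_g2
                                        + small_trait.sigma_eps2)
        assert np.mean(res) == pytest.approx(truth, abs=0.05)
        assert all(0 <= h <= 1 for h in res)


class TestMarketSegments:
    def test_single_segment_refused(self, tiny_design):
        sim = simulate_trait(tiny_design, TraitSpec("T"), seed=0)
        with pytest.raises(ReMLError):
            ladder.fit_market_segments(sim, "T")

    def test_heterogeneity_detected_when_present(self, recovery_design):
        tr = TraitSpec("T", segment_g2={"ST": 2.0, "TA": 0.5, "CR": 0.5,
                                        "FF": 0.5},
                       sigma_eps2=0.4)
        hits = 0
        for seed in range(5):
            sim = simulate_trait(recovery_design, tr, seed=4000 + seed,
                                 standardize_effects=True)
            res = ladder.fit_market_segments(sim, "T")
            est = res["segment_variances"]
            if res["heterogeneity_lrt"][1] < 0.05 and \
                    est["ST"] == max(est.values()):
                hits += 1
        assert hits >= 4  # power > 0.8 at this contrast

    def test_equal_variance_constrained_fit_matches_homogeneous(
            self, recovery_design):
        """Model-6 likelihood at equal segment variances equals the
        homogeneous fit's likelihood (parameterization consistency)."""
        tr = TraitSpec("T", sigma_g2=0.6, sigma_eps2=0.4)
        sim = simulate_trait(recovery_design, tr, seed=4100)
        df = ladder.prepare_frame(sim)
        res = ladder.fit_market_segments(sim, "T")
        hom = res["fit_hom"]
        het_spec = ladder.model_spec("model6", "T")
        pr = _MMEProblem(df, het_spec)
        # order: per-segment entries variances (sorted), then base terms
        start = []
        for i, members in enumerate(pr.vc_index):
            k, g = members[0]
            name = pr.terms[k].term.name
            if name == "entries_by_segment":
                start.append(hom.varcomp["entries"])
            else:
                v = hom.varcomp[name]
                start.append(v if v > 0 else 1e-10)
        start.append(hom.resid)
        neg2, _, _ = pr.evaluate(np.log(np.array(start)))
        assert -0.5 * neg2 == pytest.approx(hom.loglik, abs=1e-6)


@pytest.fixture(scope="module")
def population_sim(recovery_design):
    tr = TraitSpec("T", sigma_g2=0.5, sigma_p2=0.4, sigma_a2=0.1,
                   sigma_e2=0.3, sigma_ge2=0.2, sigma_b2=0.05,
                   sigma_r2=0.05, sigma_h2=0.05, sigma_eps2=0.4)
    return tr, simulate_trait(recovery_design, tr, seed=5000,
                              standardize_effects=True)


class TestPopulations:
    def test_inter_exceeds_intra_when_simulated(self, recovery_design):
        tr = TraitSpec("T", sigma_g2=0.5, sigma_p2=0.4, sigma_a2=0.1,
                       sigma_eps2=0.4)
        wins = 0
        for seed in range(10):
            sim = simulate_trait(recovery_design, tr, seed=5100 + seed,
                                 standardize_effects=True)
            dec = ladder.decompose_populations(sim, "T")
            if dec.sigma_p2 > dec.sigma_a2:
                wins += 1
        assert wins >= 9

    def test_zero_inter_population_variance_hits_boundary(
            self, recovery_design):
        tr = TraitSpec("T", sigma_g2=0.5, sigma_p2=0.0, sigma_a2=0.4,
                       sigma_eps2=0.4)
        boundary = 0
        for seed in range(6):
            sim = simulate_trait(recovery_design, tr, seed=5200 + seed)
            dec = ladder.decompose_populations(sim, "T")
            boundary += int(dec.sigma_p2 < 0.05 * dec.sigma_a2)
        assert boundary >= 4

    def test_small_families_become_single_entries(self, tiny_design):
        sim = simulate_trait(tiny_design, TraitSpec("T"), seed=1)
        with pytest.raises(ReMLError):
            ladder.decompose_populations(sim, "T", min_family=7)

    def test_heterogeneous_family_variances_reported(self, population_sim):
        _, sim = population_sim
        dec = ladder.decompose_populations(sim, "T", heterogeneous=True)
        assert dec.family_variances is not None
        assert len(dec.family_variances) == 20
        assert all(v >= 0 for v in dec.family_variances.values())
        assert dec.zero_variance_share is not None

    def test_determinism(self, population_sim):
        _, sim = population_sim
        d1 = ladder.decompose_populations(sim, "T")
        d2 = ladder.decompose_populations(sim, "T")
        assert d1.sigma_p2 == d2.sigma_p2
        assert d1.sigma_a2 == d2.sigma_a2


class TestPermutationTest:
    def test_zero_permutations_rejected(self, population_sim):
        _, sim = population_sim
        with pytest.raises(ValueError):
            ladder.permutation_test_heterogeneous_intra(sim, "T", n_perm=0)

    def test_heterogeneous_family_detected(self):
        """One family at 10x intra-variance pushes p towards zero.

        At this reduced scale (8 families x 10 clones, 3 environments)
        single-dataset power is moderate, so the check is on the p-value
        distribution across replicates rather than a per-dataset cut.
        """
        fams = tuple(FamilySpec(f"F{i}", 10, "TA") for i in range(8))
        sc = SyntheticScenario(
            n_companies=1, environments_per_company=3, n_checks=4,
            check_reps_per_env=4, families=fams, blocks_per_env=2,
            rows_per_block=8, cols_per_block=8, split_trial=False, seed=0,
        )
        d = generate_design(sc)
        tr = TraitSpec("T", sigma_g2=0.5, sigma_p2=0.0,
                       sigma_a2={f"F{i}": (2.0 if i == 0 else 0.2)
                                 for i in range(8)},
                       sigma_e2=0.2, sigma_ge2=0.1, sigma_eps2=0.3)
        ps = []
        for seed in range(8):
            sim = simulate_trait(d, tr, seed=6000 + seed)
            res = ladder.permutation_test_heterogeneous_intra(
                sim, "T", n_perm=30, seed=seed)
            ps.append(res["p"])
        # under the null the p values would centre on 0.5
        assert np.mean(ps) <= 0.3
        assert np.median(ps) <= 0.15


class TestPopulationEnvironment:
    def test_recovery_and_lrt(self, recovery_design):
        tr = TraitSpec("T", sigma_g2=0.5, sigma_p2=0.3, sigma_a2=0.3,
                       sigma_pe2=0.3, sigma_eps2=0.4)
        ests = []
        for seed in range(6):
            sim = simulate_trait(recovery_design, tr, seed=7000 + seed,
                                 standardize_effects=True)
            res = ladder.population_environment_interaction(sim, "T")
            ests.append(res["sigma_pe2"])
        assert np.mean(ests) == pytest.approx(0.3, rel=0.20)

    def test_zero_interaction_hits_boundary(self, recovery_design):
        tr = TraitSpec("T", sigma_g2=0.5, sigma_p2=0.3, sigma_a2=0.3,
                       sigma_pe2=0.0, sigma_eps2=0.4)
        boundary = 0
        for seed in range(5):
            sim = simulate_trait(recovery_design, tr, seed=7100 + seed)
            res = ladder.population_environment_interaction(sim, "T")
            total = res["fit"].total_variance()
            boundary += int(res["sigma_pe2"] < 0.02 * total)
        assert boundary >= 3

    def test_single_environment_rejected(self, tiny_design):
        sub = tiny_design[
            tiny_design["environment_id"]
            == tiny_design["environment_id"].iloc[0]
        ].reset_index(drop=True)
        sim = simulate_trait(sub, TraitSpec("T"), seed=2)
        with pytest.raises(ReMLError):
            ladder.population_environment_interaction(sim, "T")


class TestVarianceMeanAssociation:
    def test_constant_variances_undefined(self):
        assert np.isnan(ladder.variance_mean_association(
            {"a": 1.0, "b": 1.0, "c": 1.0},
            pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})))

    def test_sign_flip_antisymmetry(self):
        v = {"a": 0.1, "b": 0.4, "c": 0.9}
        m = pd.Series({"a": 1.0, "b": 2.0, "c": 4.0})
        r1 = ladder.variance_mean_association(v, m)
        r2 = ladder.variance_mean_association(v, -m)
        assert r1 == pytest.approx(-r2)

    def test_linear_link_recovered(self):
        rng = np.random.default_rng(0)
        means = pd.Series(rng.uniform(1, 9, 30),
                          index=[f"f{i}" for i in range(30)])
        variances = {f: 0.1 + 0.05 * means[f] + rng.normal(0, 0.01)
                     for f in means.index}
        assert ladder.variance_mean_association(variances, means) > 0.5

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError):
            ladder.variance_mean_association({"a": 1.0}, pd.Series({"a": 1.0}))


class TestTraitClassEnrichment:
    def test_matches_hypergeometric_enumeration(self):
        """Fisher's exact p equals the two-sided hypergeometric sum."""
        inter_higher = {f"t{i}": i < 8 for i in range(20)}
        classes = {f"t{i}": ("quality" if i % 3 == 0 else "agronomic")
                   for i in range(20)}
        odds, p = ladder.trait_class_enrichment(inter_higher, classes)
        # independent oracle: enumerate the 2x2 table distribution
        q_total = sum(1 for t in classes.values() if t == "quality")
        hi_total = sum(inter_higher.values())
        n = len(classes)
        q_hi = sum(1 for t, h in inter_higher.items()
                   if h and classes[t] == "quality")
        rv = hypergeom(n, q_total, hi_total)
        p_obs = rv.pmf(q_hi)
        p_oracle = sum(rv.pmf(k) for k in range(rv.support()[0],
                                                rv.support()[1] + 1)
                       if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(p_oracle, abs=1e-10)
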