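"""Season allocation, within-trial REML, heritability, chained scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolgs.phenotypes import (
    PhenotypeError,
    VarianceComponents,
    allocate_harvests_to_seasons,
    chain_scale_to_reference,
    combine_across_trials,
    estimate_heritability,
    fit_within_trial,
    season_of_month,
)
from poolgs.simulate import SimulationConfig, simulate_program


class TestSeasonAllocation:
    def test_five_seasons_partition_the_year(self):
        seasons = [season_of_month(m) for m in range(1, 13)]
        assert set(seasons) == {"autumn", "winter", "early_spring", "late_spring", "summer"}

    def test_window_within_single_season(self):
        labels = allocate_harvests_to_seasons(["2005-11-15"], "2005-10-01")
        assert labels == ["late_spring"]

    def test_day_counting_across_boundary(self):
        # growth window 21 May - 20 Jul: 11 autumn days vs 50 winter days
        labels = allocate_harvests_to_seasons(["2005-07-20"], "2005-05-20")
        assert labels == ["winter"]

    def test_tie_broken_toward_harvest_date_season(self):
        # 21-30 Nov (10 late-spring days) vs 1-10 Dec (10 summer days)
        labels = allocate_harvests_to_seasons(["2005-12-10"], "2005-11-20")
        assert labels == ["summer"]

    def test_windows_chain_between_harvests(self):
        labels = allocate_harvests_to_seasons(["2005-05-20", "2005-07-20"], "2005-04-01")
        assert labels == ["autumn", "winter"]

    def test_undated_harvest_rejected(self):
        with pytest.raises(PhenotypeError):
            allocate_harvests_to_seasons(["2005-05-20", None], "2005-04-01")


def _balanced_trial(rng, n_pops=12, n_blocks=3, sigma_b=1.0, sigma_e=1.5, reps_scale=1):
    pops = [f"P{i}" for i in range(n_pops)]
    truth = rng.normal(0, 2, n_pops)
    rows = []
    for b in range(n_blocks):
        beff = rng.normal(0, sigma_b) if sigma_b > 0 else 0.0
        for rep in range(reps_scale):
            for i, p in enumerate(pops):
                rows.append((p, f"b{b}", truth[i] + beff + rng.normal(0, sigma_e)))
    return pd.DataFrame(rows, columns=["population", "block", "value"]), truth


class TestWithinTrialREML:
    def test_balanced_design_blues_equal_raw_means(self, rng):
        df, _ = _balanced_trial(rng)
        means, _, _ = fit_within_trial(df)
        raw = df.groupby("population", sort=False)["value"].mean()
        np.testing.assert_allclose(means[raw.index], raw, atol=1e-6)

    def test_duplicating_data_doubles_weights(self, rng):
        df, _ = _balanced_trial(rng)
        _, w1, _ = fit_within_trial(df)
        df2 = pd.concat([df, df], ignore_index=True)
        _, w2, _ = fit_within_trial(df2)
        ratio = (w2 / w1).to_numpy()
        assert np.all(np.abs(ratio - 2.0) < 0.3)

    def test_variance_component_recovery(self):
        """sigma2_block=1, sigma2_error=2 recovered within +/-20% at 25x3.

        The 2-df block component is heavily skewed, so the average is taken
        over 200 replicate trials to keep Monte Carlo error well inside the
        band."""
        rng = np.random.default_rng(0)
        sb, se = [], []
        for _ in range(200):
            df, _ = _balanced_trial(
                rng, n_pops=25, n_blocks=3, sigma_b=1.0, sigma_e=np.sqrt(2.0)
            )
            _, _, vc = fit_within_trial(df)
            sb.append(vc.sigma2_block)
            se.append(vc.sigma2_error)
        assert abs(np.mean(sb) - 1.0) < 0.2
        assert abs(np.mean(se) - 2.0) < 0.4

    def test_too_few_populations_or_blocks(self, rng):
        df, _ = _balanced_trial(rng, n_pops=1)
        with pytest.raises(PhenotypeError):
            fit_within_trial(df)
        df, _ = _balanced_trial(rng, n_blocks=1)
        with pytest.raises(PhenotypeError):
            fit_within_trial(df)


class TestHeritability:
    def test_arithmetic(self):
        vc = VarianceComponents(0.0, 1.0, 1.0, 1)
        assert estimate_heritability(vc, 1) == pytest.approx(0.5)
        assert estimate_heritability(VarianceComponents(0.0, 0.0, 1.0, 1), 3) == 0.0

    def test_more_reps_increase_line_heritability(self):
        vc = VarianceComponents(0.0, 1.0, 2.0, 1)
        assert estimate_heritability(vc, 6) > estimate_heritability(vc, 1)

    def test_all_zero_components_error(self):
        with pytest.raises(PhenotypeError):
            estimate_heritability(VarianceComponents(0.0, 0.0, 0.0, 1), 3)


def _stage1_two_eras(rng, offset=1.5, noise=0.05):
    """Stage-1 table with anchors A1 (era 1, years 1-2) and A2 (era 2, year 3).

    True values: anchor A1 = 0, anchor A2 = ``offset``; era-2 populations have
    known truth so recovery of the chained offset can be checked.
    """
    rows = []
    truth = {"A1": 0.0, "A2": offset}
    for t, year in (("T1", 1), ("T2", 2), ("T3", 3)):
        mu = rng.normal(0, 2.0)  # trial effect removed by anchoring
        pops = ["A1", "A2"] if year <= 2 else ["A2"]
        pops = pops + [f"P{year}{i}" for i in range(6)]
        for p in pops:
            if p not in truth:
                truth[p] = rng.normal(offset if year == 3 else 0.0, 1.0)
            rows.append(
                (p, t, year, "average", truth[p] + mu + rng.normal(0, noise), 1.0 / noise ** 2)
            )
    df = pd.DataFrame(
        rows, columns=["population", "trial_id", "sowing_year", "season", "value", "weight"]
    )
    return df, truth


class TestChainScaling:
    def test_single_era_anchor_zero_everywhere(self, rng):
        df, _ = _stage1_two_eras(rng)
        df = df[df.sowing_year <= 2]
        scaled, _ = chain_scale_to_reference(df, [("A1", 1, 2)])
        anchor = scaled[scaled.population == "A1"]
        np.testing.assert_allclose(anchor["value"], 0.0, atol=1e-12)

    def test_noise_free_chaining_exact(self, rng):
        df, truth = _stage1_two_eras(rng, offset=1.5, noise=1e-12)
        scaled, offsets = chain_scale_to_reference(df, [("A1", 1, 2), ("A2", 3, 3)])
        assert offsets["offset"]["A2"]["average"] == pytest.approx(1.5, abs=1e-6)
        for _, row in scaled.iterrows():
            assert row["value"] == pytest.approx(truth[row["population"]], abs=1e-6)

    def test_simulated_offset_recovered_within_interval(self):
        rng = np.random.default_rng(42)
        df, _ = _stage1_two_eras(rng, offset=1.5, noise=0.2)
        _, offsets = chain_scale_to_reference(df, [("A1", 1, 2), ("A2", 3, 3)])
        est = offsets["offset"]["A2"]["average"]
        se = offsets["se"]["A2"]["average"]
        assert abs(est - 1.5) < max(3 * se, 0.3)

    def test_broken_link_raises(self, rng):
        df, _ = _stage1_two_eras(rng)
        df = df[df.population != "A2"]
        with pytest.raises(PhenotypeError):
            chain_scale_to_reference(df, [("A1", 1, 2), ("A2", 3, 3)])


class TestCombineAcrossTrials:
    def test_shrinkage_toward_zero_for_single_trial_population(self, rng):
        rows = [("P1", 2.0, 1.0)] + [(f"Q{i}", rng.normal(0, 1.5), 1.0) for i in range(30)]
        df = pd.DataFrame(rows, columns=["population", "value", "weight"])
        out = combine_across_trials(df).set_index("population")
        assert 0.0 < out.loc["P1", "value"] < 2.0

    def test_two_equal_weight_records_bracket(self, rng):
        rows = [("P1", 1.0, 1.0), ("P1", 3.0, 1.0)]
        rows += [(f"Q{i}", rng.normal(0, 2.0), 1.0) for i in range(30)]
        df = pd.DataFrame(rows, columns=["population", "value", "weight"])
        out = combine_across_trials(df).set_index("population")
        assert 0.0 < out.loc["P1", "value"] < 3.0

    def test_nonpositive_weights_rejected(self):
        df = pd.DataFrame(
            {"population": ["P1", "P2"], "value": [1.0, 2.0], "weight": [1.0, 0.0]}
        )
        with pytest.raises(PhenotypeError):
            combine_across_trials(df)

    def test_noise_free_combination_is_weighted_mean(self):
        df = pd.DataFrame(
            {
                "population": ["P1", "P1", "P2"],
                "value": [2.0, 2.0, -1.0],
                "weight": [1.0, 3.0, 2.0],
            }
        )
        out = combine_across_trials(df).set_index("population")
        assert out.loc["P1", "value"] == pytest.approx(2.0)
        assert out.loc["P2", "value"] == pytest.approx(-1.0)


class TestTwoStagePipeline:
    def test_noise_free_rankings_match_truth(self):
        from poolgs.phenotypes import adjust_phenotypes

        cfg = SimulationConfig(
            n_years=3,
            populations_per_year=8,
            n_loci=200,
            n_founders_per_group=40,
            n_qtl_biomass=30,
            n_qtl_heading=5,
            group_b_start_year=4,
            residual_scale=0.0,
            seed=13,
        )
        sim = simulate_program(cfg)
        adj = adjust_phenotypes(sim.phenotypes, sim.reference_chain, trait="heading")
        v = adj.values.set_index("population")["value"]
        truth = sim.truth.true_breeding_values.loc[v.index, "heading"]
        rho = stats.spearmanr(v, truth).statistic
        assert rho > 0.999

    def test_anchor_final_value_zero_in_noise_free_data(self):
        from poolgs.phenotypes import adjust_phenotypes

        cfg = SimulationConfig(
            n_years=3,
            populations_per_year=8,
            n_loci=200,
            n_founders_per_group=40,
            n_qtl_biomass=30,
            n_qtl_heading=5,
            group_b_start_year=4,
            residual_scale=0.0,
            seed=13,
        )
        sim = simulate_program(cfg)
        adj = adjust_phenotypes(sim.phenotypes, sim.reference_chain, trait="biomass")
        anchor = sim.reference_chain[0][0]
        vals = adj.values[adj.values.population == anchor]["value"]
        np.testing.assert_allclose(vals, 0.0, atol=1e-8)

    def test_rank_recovery_scales_with_heritability(self, small_sim):
        from poolgs.phenotypes import adjust_phenotypes

        adj_h = adjust_phenotypes(small_sim.phenotypes, small_sim.reference_chain, "heading")
        adj_b = adjust_phenotypes(small_sim.phenotypes, small_sim.reference_chain, "biomass")
        truth = small_sim.truth.true_breeding_values
        vh = adj_h.values.set_index("population")["value"]
        rho_h = stats.spearmanr(vh, truth.loc[vh.index, "heading"]).statistic
        vb = adj_b.values[adj_b.values.season == "average"].set_index("population")["value"]
        rho_b = stats.spearmanr(vb, truth.loc[vb.index, "biomass_average"]).statistic
        assert rho_h > 0.8
        assert rho_b > 0.5
        assert rho_h > rho_b
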