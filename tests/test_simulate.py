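"""Tests of the breeding-program generator against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from poolgs.phenotypes import seasonal_records
from poolgs.simulate import (
    ConfigurationError,
    SimulationConfig,
    form_population,
    simulate_founders,
    simulate_pool_reads,
    simulate_program,
)


def hudson_fst(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Hudson's Fst estimator (ratio of averages) from haplotype matrices."""
    p1 = hap_a.mean(axis=0)
    p2 = hap_b.mean(axis=0)
    n1, n2 = hap_a.shape[0], hap_b.shape[0]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


class TestFounders:
    def test_realised_fst_matches_divergence(self):
        cfg = SimulationConfig(
            n_loci=10000, n_founders_per_group=200, group_divergence=0.3, seed=11
        )
        f = simulate_founders(cfg)
        fst = hudson_fst(f.haplotypes["A"], f.haplotypes["B"])
        assert abs(fst - 0.3) < 0.05

    def test_no_divergence_gives_near_zero_fst(self):
        cfg = SimulationConfig(
            n_loci=5000, n_founders_per_group=200, group_divergence=1e-4, seed=3
        )
        f = simulate_founders(cfg)
        assert abs(hudson_fst(f.haplotypes["A"], f.haplotypes["B"])) < 0.02

    def test_same_seed_identical_pools(self, small_config):
        f1 = simulate_founders(small_config)
        f2 = simulate_founders(small_config)
        for g in ("A", "B"):
            np.testing.assert_array_equal(f1.haplotypes[g], f2.haplotypes[g])

    def test_ld_decays_with_map_distance(self, small_config):
        f = simulate_founders(small_config)
        h = f.haplotypes["A"].astype(float)
        same_chrom = f.chrom[:-1] == f.chrom[1:]

        def mean_r(lag):
            rs = []
            for j in range(0, h.shape[1] - lag, 5):
                if f.chrom[j] != f.chrom[j + lag]:
                    continue
                a, b = h[:, j], h[:, j + lag]
                if a.std() == 0 or b.std() == 0:
                    continue
                rs.append(abs(np.corrcoef(a, b)[0, 1]))
            return np.mean(rs)

        assert same_chrom.any()
        assert mean_r(1) > mean_r(20)

    def test_invalid_divergence_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_founders(SimulationConfig(group_divergence=0.0))
        with pytest.raises(ConfigurationError):
            simulate_founders(SimulationConfig(group_divergence=1.0))


class TestProgram:
    def test_identical_parents_closure(self, rng):
        parent = rng.uniform(0, 1, 50)
        np.testing.assert_array_equal(form_population(np.tile(parent, (4, 1))), parent)

    def test_determinism_under_fixed_seed(self, small_config, small_sim):
        sim2 = simulate_program(small_config)
        np.testing.assert_array_equal(sim2.truth.true_af.af, small_sim.truth.true_af.af)
        np.testing.assert_array_equal(sim2.read_counts.ref_depth, small_sim.read_counts.ref_depth)
        pd.testing.assert_frame_equal(sim2.phenotypes, small_sim.phenotypes)

    def test_every_population_has_group_and_af_in_range(self, small_sim):
        afm = small_sim.truth.true_af
        assert set(afm.populations) == set(small_sim.truth.group_of)
        assert np.all((afm.af >= 0) & (afm.af <= 1))
        assert set(small_sim.truth.group_of.values()) <= {"A", "B"}

    def test_group_b_enters_late(self, small_sim):
        meta = small_sim.metadata
        early = meta[(meta.sowing_year >= 1) & (meta.sowing_year < 4)]
        late = meta[meta.sowing_year >= 4]
        assert (early.group == "A").all()
        assert (late.group == "B").any()

    def test_invalid_group_b_start_year(self):
        with pytest.raises(ConfigurationError):
            simulate_program(SimulationConfig(n_years=5, group_b_start_year=9))

    def test_noise_free_plot_means_equal_breeding_values(self):
        cfg = SimulationConfig(
            n_years=2,
            populations_per_year=8,
            n_loci=200,
            n_founders_per_group=40,
            n_qtl_biomass=30,
            n_qtl_heading=5,
            group_b_start_year=3,
            residual_scale=0.0,
            seed=5,
        )
        sim = simulate_program(cfg)
        records = seasonal_records(sim.phenotypes, trait="biomass")
        avg = records[records.season == "average"]
        for trial_id, sub in avg.groupby("trial_id"):
            means = sub.groupby("population")["value"].mean()
            truth = sim.truth.true_breeding_values.loc[means.index, "biomass_average"]
            r = np.corrcoef(means, truth)[0, 1]
            assert r > 1 - 1e-9

    def test_recycling_creates_relatedness(self, small_sim, small_config):
        """Later-year populations are closer to earlier ones of the same
        program than to populations from an independent program."""
        from poolgs.relationship import compute_grm

        other = simulate_program(
            SimulationConfig(**{**small_config.__dict__, "seed": 99})
        )
        meta = small_sim.metadata.set_index("population")
        late = [
            p
            for p in small_sim.truth.true_af.populations
            if not meta.loc[p, "is_check"]
            and meta.loc[p, "sowing_year"] >= 5
            and meta.loc[p, "group"] == "A"
        ]
        early = [
            p
            for p in small_sim.truth.true_af.populations
            if not meta.loc[p, "is_check"]
            and 1 <= meta.loc[p, "sowing_year"] <= 2
            and meta.loc[p, "group"] == "A"
        ]
        other_meta = other.metadata.set_index("population")
        unrelated = [
            p
            for p in other.truth.true_af.populations
            if not other_meta.loc[p, "is_check"] and other_meta.loc[p, "group"] == "A"
        ][: len(early)]
        afm = small_sim.truth.true_af
        af_stack = np.vstack(
            [
                afm.af[afm.population_index(late)],
                afm.af[afm.population_index(early)],
                other.truth.true_af.af[other.truth.true_af.population_index(unrelated)],
            ]
        )
        grm = compute_grm(af_stack)
        nl, ne = len(late), len(early)
        g_late_early = grm.G[:nl, nl: nl + ne].mean()
        g_late_unrel = grm.G[:nl, nl + ne:].mean()
        assert g_late_early > g_late_unrel


class TestPoolReads:
    def test_fixed_allele_gives_pure_reference_reads(self):
        rcm = simulate_pool_reads(np.ones((1, 50)), depth_mean=200.0, seed=1)
        assert np.array_equal(rcm.alt_depth, np.zeros_like(rcm.alt_depth))
        total = rcm.total_depth
        with np.errstate(invalid="ignore"):
            af = rcm.ref_depth / np.where(total > 0, total, 1)
        assert np.all(af[total > 0] == 1.0)

    def test_mean_observed_af_unbiased(self):
        rcm = simulate_pool_reads(np.full((1, 10000), 0.5), depth_mean=200.0, seed=2)
        total = rcm.total_depth.astype(float)
        af = rcm.ref_depth[total > 0] / total[total > 0]
        assert 0.49 < af.mean() < 0.51

    def test_observed_af_converges_to_truth_with_depth(self, rng):
        true_af = rng.uniform(0.05, 0.95, size=(5, 400))
        rcm = simulate_pool_reads(true_af, depth_mean=5000.0, seed=3, pool_size=5000)
        obs = rcm.ref_depth / rcm.total_depth
        slope = np.polyfit(true_af.ravel(), obs.ravel(), 1)[0]
        assert abs(slope - 1.0) < 0.02

    def test_low_depth_triggers_missing_downstream(self):
        from poolgs.genotyping import compute_allele_frequencies

        rcm = simulate_pool_reads(np.full((4, 500), 0.5), depth_mean=1.0, seed=4)
        afm = compute_allele_frequencies(rcm, min_call_depth=40)
        assert afm.missing.mean() > 0.9

    def test_invalid_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_pool_reads(np.full((1, 5), 0.5), depth_mean=0.0, seed=1)


class TestHeritabilityCalibration:
    def test_realised_heading_heritability_near_target(self):
        """Target H2 = 0.86 with 25 populations x 3 reps is recovered by the
        within-trial estimator, averaged over replicate simulations."""
        from poolgs.phenotypes import estimate_heritability, fit_within_trial

        estimates = []
        for seed in range(50):
            cfg = SimulationConfig(
                n_years=1,
                populations_per_year=25,
                n_trials_per_year=1,
                n_loci=150,
                n_founders_per_group=30,
                n_qtl_biomass=20,
                n_qtl_heading=6,
                group_b_start_year=2,
                h2_heading=0.86,
                seed=1000 + seed,
            )
            sim = simulate_program(cfg)
            records = seasonal_records(sim.phenotypes, trait="heading")
            trial = records[records.trial_id == records.trial_id.iloc[0]]
            _, _, vc = fit_within_trial(trial)
            estimates.append(estimate_heritability(vc, vc.n_effective_reps))
        assert 0.70 < float(np.mean(estimates)) < 0.95
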