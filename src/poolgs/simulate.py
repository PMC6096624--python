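"""Synthetic breeding-program generator with known ground truth.

Emulates a commercial forage breeding program in which new synthetic
populations are created every year by intercrossing 4-6 parents, trialled as
replicated sward plots for two production years, and genotyped as pools of
germinated seed.  The generator produces:

- two diverged founder germplasm groups (an adapted main pool and a second,
  later-introduced pool) with linkage disequilibrium along a linear map;
- yearly synthetic populations whose parents are recycled elite populations
  from 3-6 years earlier, creating the cyclic relatedness typical of such
  programs;
- exact population allele frequencies (the ground truth for genotyping and
  imputation) and true breeding values per trait and season;
- pooled sequencing read counts (negative-binomial depth, binomial allele
  sampling on top of finite-pool construction noise);
- long-format trial phenotypes for a seasonal biomass trait (many small
  marker effects, moderate heritability) and a heading-date-like trait
  (few large effects, high heritability), with reference-check cultivars
  whose eras overlap so that cross-era scaling can be exercised.

Causal loci are part of the genotyped panel by default (a transcriptome-based
assay is expected to include causal gene variants); set ``qtl_in_panel``
False to leave them out so markers tag them only through linkage
disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from poolgs.genotyping import AlleleFrequencyMatrix, ReadCountMatrix

SEASONS = ("autumn", "winter", "early_spring", "late_spring", "summer")

#: Default plot-level heritability targets per season for the biomass-like
#: trait (seasonal means in the 0.05-0.81 range typical of sward yield
#: trials; overall mean ~0.44) and for the heading-date-like trait (0.86).
DEFAULT_H2_BIOMASS = {
    "autumn": 0.43,
    "winter": 0.55,
    "early_spring": 0.55,
    "late_spring": 0.41,
    "summer": 0.26,
}
DEFAULT_H2_HEADING = 0.86

_BASES = ("A", "C", "G", "T")
_N_CHROM = 7


class ConfigurationError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic breeding program.

    Defaults describe a 10-year program of ~24 new synthetic populations per
    year split over two annual trials with threefold replication, pooled
    sequencing of 60 germinants at ~150x mean depth, and the second
    germplasm group entering the program from year 5.
    """

    n_years: int = 10
    populations_per_year: int = 24
    n_loci: int = 600
    n_founders_per_group: int = 100
    group_divergence: float = 0.3
    parents_min: int = 4
    parents_max: int = 6
    pool_size: int = 60
    depth_mean: float = 300.0
    depth_dispersion: float = 1.0
    h2_by_season: dict = field(default_factory=lambda: dict(DEFAULT_H2_BIOMASS))
    h2_heading: float = DEFAULT_H2_HEADING
    n_replicates: int = 3
    n_trials_per_year: int = 2
    group_b_start_year: int = 5
    group_b_fraction: float = 0.25
    ld_decay: float = 30.0
    n_qtl_biomass: int = 90
    n_qtl_heading: int = 10
    qtl_in_panel: bool = True
    season_effect_correlation: float = 0.5
    cross_group_correlation_biomass: float = 0.0
    cross_group_correlation_heading: float = 0.8
    group_b_shift_sd: float = 0.0
    residual_scale: float = 1.0
    trial_sd_scale: float = 0.5
    block_sd_scale: float = 0.5
    elite_fraction: float = 0.5
    parent_year_gap: tuple = (3, 6)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.group_divergence < 1.0):
            raise ConfigurationError(
                f"group_divergence must be in (0, 1), got {self.group_divergence}"
            )
        if not (4 <= self.parents_min <= self.parents_max <= 6):
            raise ConfigurationError("parents per cross must lie in [4, 6]")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.n_loci < 2:
            raise ConfigurationError("n_loci must be >= 2")
        h2s = list(self.h2_by_season.values()) + [self.h2_heading]
        if not all(0.0 < h < 1.0 for h in h2s):
            raise ConfigurationError("all heritabilities must be in (0, 1)")
        if not (1 <= self.group_b_start_year <= self.n_years + 1):
            raise ConfigurationError(
                f"group_b_start_year {self.group_b_start_year} outside simulated "
                f"range 1..{self.n_years + 1}"
            )
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.pool_size < 1:
            raise ConfigurationError("pool_size must be >= 1")


@dataclass
class FounderPool:
    """Diploid founder genotypes per germplasm group on a linear map."""

    positions: np.ndarray
    chrom: np.ndarray
    haplotypes: dict[str, np.ndarray]
    group_freqs: dict[str, np.ndarray]

    def founder_af(self, group: str, founder_index: int) -> np.ndarray:
        """Allele frequency vector of a single diploid founder (dosage / 2)."""
        h = self.haplotypes[group]
        return (h[2 * founder_index] + h[2 * founder_index + 1]) / 2.0


@dataclass
class TruthSet:
    """Ground truth of the simulated program (marker loci only in true_af)."""

    true_af: AlleleFrequencyMatrix
    true_breeding_values: pd.DataFrame
    group_of: dict[str, str]


@dataclass
class SimulationResult:
    truth: TruthSet
    read_counts: ReadCountMatrix
    phenotypes: pd.DataFrame
    metadata: pd.DataFrame
    reference_chain: list
    config: SimulationConfig


def _locus_map(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Unit-spaced positions split over equally sized chromosomes."""
    positions = np.arange(config.n_loci, dtype=float)
    chrom = np.minimum(
        (np.arange(config.n_loci) * _N_CHROM) // config.n_loci, _N_CHROM - 1
    ).astype(int)
    return positions, chrom


def _ar1_latent(rng, n_series, positions, chrom, decay) -> np.ndarray:
    """Stationary AR(1) Gaussian field along the map; resets at chromosome ends."""
    m = positions.shape[0]
    z = np.empty((n_series, m))
    z[:, 0] = rng.standard_normal(n_series)
    for j in range(1, m):
        if chrom[j] != chrom[j - 1]:
            rho = 0.0
        else:
            rho = np.exp(-(positions[j] - positions[j - 1]) / decay)
        z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n_series)
    return z


def simulate_founders(config: SimulationConfig, rng: np.random.Generator | None = None) -> FounderPool:
    """Generate two diverged diploid founder pools with LD along a linear map.

    Ancestral allele frequencies and group-specific deviations are drawn from
    a Gaussian copula with exponential correlation decay along the map; the
    group deviation follows the Balding-Nichols model, so the expected
    between-group differentiation (Hudson-type Fst) equals
    ``group_divergence``.  Founder haplotypes are thresholded from the same
    copula, giving within-group LD that decays with map distance.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    positions, chrom = _locus_map(config)
    F = config.group_divergence

    latent0 = _ar1_latent(rng, 1, positions, chrom, config.ld_decay)[0]
    p0 = 0.05 + 0.90 * stats.norm.cdf(latent0)

    group_freqs: dict[str, np.ndarray] = {}
    haplotypes: dict[str, np.ndarray] = {}
    for group in ("A", "B"):
        u = _ar1_latent(rng, 1, positions, chrom, config.ld_decay)[0]
        if F < 1e-9:
            p_g = p0.copy()
        else:
            a = p0 * (1.0 - F) / F
            b = (1.0 - p0) * (1.0 - F) / F
            p_g = stats.beta.ppf(stats.norm.cdf(u), a, b)
        p_g = np.clip(p_g, 1e-4, 1.0 - 1e-4)
        group_freqs[group] = p_g
        z = _ar1_latent(rng, 2 * config.n_founders_per_group, positions, chrom, config.ld_decay)
        thresh = stats.norm.ppf(p_g)
        haplotypes[group] = (z < thresh[None, :]).astype(np.int8)
    return FounderPool(positions=positions, chrom=chrom, haplotypes=haplotypes, group_freqs=group_freqs)


def _sample_plant_af(
    af: np.ndarray,
    positions: np.ndarray,
    chrom: np.ndarray,
    decay: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele-frequency contribution (dosage / 2) of one diploid plant drawn
    from a segregating population with frequencies ``af``.

    Haplotypes are thresholded from the AR(1) Gaussian copula along the map,
    so linked loci co-segregate as in a real gamete.  Sampling individual
    parent plants is what regenerates between-population genetic variance
    from within-population heterozygosity in each breeding cycle.
    """
    z = _ar1_latent(rng, 2, positions, chrom, decay)
    thresh = stats.norm.ppf(np.clip(af, 1e-6, 1.0 - 1e-6))
    hap = (z < thresh[None, :]).astype(np.int8)
    return (hap[0] + hap[1]) / 2.0


def form_population(parent_afs: np.ndarray) -> np.ndarray:
    """Exact allele frequencies of a synthetic formed by equal intercrossing.

    Under random mating among equal parental contributions the population
    frequency is the mean of the parents' frequencies; a cross of identical
    parents therefore reproduces the parent exactly.
    """
    parent_afs = np.atleast_2d(np.asarray(parent_afs, dtype=float))
    return parent_afs.mean(axis=0)


def _locus_ids(positions: np.ndarray, chrom: np.ndarray, rng: np.random.Generator) -> list[str]:
    ids = []
    pos_within = np.zeros(len(positions), dtype=int)
    counter: dict[int, int] = {}
    for j, c in enumerate(chrom):
        counter[c] = counter.get(c, 0) + 1
        pos_within[j] = counter[c]
    ref_idx = rng.integers(0, 4, size=len(positions))
    alt_shift = rng.integers(1, 4, size=len(positions))
    for j, c in enumerate(chrom):
        ref = _BASES[ref_idx[j]]
        alt = _BASES[(ref_idx[j] + alt_shift[j]) % 4]
        ids.append(f"chr{c + 1}:{pos_within[j] * 100}:{ref}:{alt}")
    return ids


def simulate_pool_reads(
    true_af,
    depth_mean: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    pool_size: int = 60,
    dispersion: float = 2.0,
) -> ReadCountMatrix:
    """Pooled sequencing read counts from true population allele frequencies.

    A pool of ``2 * pool_size`` gene copies is first resampled binomially
    from the true frequency (pool-construction noise), total depth per locus
    per pool is negative-binomial with the given mean and gamma ``dispersion``
    (shape; smaller = more overdispersed), and reference reads are binomial
    in the pool frequency.
    """
    if depth_mean <= 0:
        raise ConfigurationError(f"depth_mean must be > 0, got {depth_mean}")
    if isinstance(true_af, AlleleFrequencyMatrix):
        af = true_af.af
        populations = list(true_af.populations)
        loci = list(true_af.loci)
    else:
        af = np.atleast_2d(np.asarray(true_af, dtype=float))
        populations = [f"POP{i + 1}" for i in range(af.shape[0])]
        loci = [f"chr1:{(j + 1) * 100}:A:G" for j in range(af.shape[1])]
    if np.any((af < 0) | (af > 1)):
        raise ConfigurationError("true allele frequencies must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    copies = 2 * pool_size
    pool_af = rng.binomial(copies, af) / copies
    lam = rng.gamma(shape=dispersion, scale=depth_mean / dispersion, size=af.shape)
    depth = rng.poisson(lam)
    ref = rng.binomial(depth, pool_af)
    return ReadCountMatrix(
        populations=populations, loci=loci, ref_depth=ref, alt_depth=depth - ref
    )


def reference_chain(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """Era plan of the reference-check cultivars: (name, first_year, last_year).

    Three checks with overlapping eras when the program is long enough
    (mirroring a chain of successively adopted commercial standards),
    otherwise a single check spanning all years.
    """
    n = config.n_years
    if n < 6:
        return [("CHK1", 1, n)]
    e1_end = max(2, int(round(0.6 * n)))
    e2_start = e1_end - 1
    e2_end = min(n, int(round(0.9 * n)))
    e3_start = e2_end - 1
    return [("CHK1", 1, e1_end), ("CHK2", e2_start, e2_end), ("CHK3", e3_start, n)]


_HARVEST_OFFSETS = (50, 116, 178, 239, 325, 362)


def _harvest_schedule(sowing: pd.Timestamp) -> list[tuple[int, pd.Timestamp]]:
    """(production_year, date) pairs for the two-year harvest schedule."""
    out = []
    for py in (1, 2):
        start = sowing + pd.DateOffset(years=py - 1)
        for off in _HARVEST_OFFSETS:
            out.append((py, start + pd.Timedelta(days=off)))
    return out


def simulate_program(config: SimulationConfig) -> SimulationResult:
    """Run the full breeding-program simulation.

    Returns ground truth (exact allele frequencies at genotyped marker loci,
    true breeding values per trait/season, group membership), pooled read
    counts, the long-format phenotype table and per-population metadata.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0])
    rng_founders, rng_qtl, rng_program, rng_pheno, rng_reads = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    founders = simulate_founders(config, rng=rng_founders)
    n_loci = config.n_loci

    # Causal loci drawn from the map.  With ``qtl_in_panel`` (default) they
    # are part of the genotyped assay, as expected for transcriptome-based
    # genotyping; otherwise markers tag them only through LD.
    n_qtl = config.n_qtl_biomass + config.n_qtl_heading
    if n_qtl >= n_loci:
        raise ConfigurationError("n_loci must exceed the number of causal loci")
    # Causal variants are sampled at intermediate frequency: loci near
    # fixation contribute negligible genetic variance (proportional to
    # heterozygosity) and would not be seen as trait loci in the program.
    mean_freq = 0.5 * (founders.group_freqs["A"] + founders.group_freqs["B"])
    eligible_qtl = np.flatnonzero((mean_freq >= 0.2) & (mean_freq <= 0.8))
    if eligible_qtl.size < n_qtl:
        eligible_qtl = np.arange(n_loci)
    qtl_all = rng_qtl.choice(eligible_qtl, size=n_qtl, replace=False)
    qtl_biomass = np.sort(qtl_all[: config.n_qtl_biomass])
    qtl_heading = np.sort(qtl_all[config.n_qtl_biomass:])
    if config.qtl_in_panel:
        marker_idx = np.arange(n_loci)
    else:
        marker_idx = np.setdiff1d(np.arange(n_loci), qtl_all)

    r = config.season_effect_correlation
    base = rng_qtl.standard_normal(config.n_qtl_biomass)
    beta_biomass = {
        "A": {
            s: np.sqrt(r) * base + np.sqrt(1.0 - r) * rng_qtl.standard_normal(config.n_qtl_biomass)
            for s in SEASONS
        }
    }
    beta_heading = {"A": rng_qtl.standard_normal(config.n_qtl_heading)}
    # Distinct genetic backgrounds: marker effects are imperfectly correlated
    # across the two germplasm groups (epistatic background differences), so
    # effects estimated in one group transfer only partially to the other --
    # weakly for the polygenic biomass trait, strongly for heading date.
    rb = config.cross_group_correlation_biomass
    rh = config.cross_group_correlation_heading
    beta_biomass["B"] = {
        s: rb * beta_biomass["A"][s]
        + np.sqrt(1.0 - rb ** 2) * rng_qtl.standard_normal(config.n_qtl_biomass)
        for s in SEASONS
    }
    beta_heading["B"] = rh * beta_heading["A"] + np.sqrt(1.0 - rh ** 2) * rng_qtl.standard_normal(
        config.n_qtl_heading
    )

    # --- populations ---------------------------------------------------
    pop_af: dict[str, np.ndarray] = {}
    group_of: dict[str, str] = {}
    sowing_year: dict[str, int] = {}
    is_check: dict[str, bool] = {}

    def found_from_founders(group: str, n_parents: int) -> np.ndarray:
        idx = rng_program.choice(config.n_founders_per_group, size=n_parents, replace=False)
        return form_population(np.stack([founders.founder_af(group, i) for i in idx]))

    chain = reference_chain(config)
    for name, _, _ in chain:
        pop_af[name] = found_from_founders("A", config.parents_max)
        group_of[name] = "A"
        sowing_year[name] = 0
        is_check[name] = True

    def tbv_index(name: str) -> float:
        af = pop_af[name]
        betas = beta_biomass[group_of[name]]
        return float(np.mean([2.0 * af[qtl_biomass] @ betas[s] for s in SEASONS]))

    gap_lo, gap_hi = config.parent_year_gap
    year_members: dict[int, list[str]] = {}
    for year in range(1, config.n_years + 1):
        n_new = config.populations_per_year
        if year >= config.group_b_start_year:
            n_b = int(round(config.group_b_fraction * n_new))
        else:
            n_b = 0
        groups = ["A"] * (n_new - n_b) + ["B"] * n_b
        names = []
        for i, grp in enumerate(groups):
            name = f"P{year:02d}_{i + 1:02d}"
            n_par = int(rng_program.integers(config.parents_min, config.parents_max + 1))
            eligible = [
                p
                for p in pop_af
                if (not is_check[p])
                and group_of[p] == grp
                and (year - gap_hi) <= sowing_year[p] <= (year - gap_lo)
            ]
            if len(eligible) >= n_par:
                # elite recycling: parent populations drawn from the top
                # fraction by index; one plant is sampled from each, so the
                # cross segregates rather than just averaging frequencies
                ranked = sorted(eligible, key=tbv_index, reverse=True)
                n_top = max(n_par, int(np.ceil(config.elite_fraction * len(ranked))))
                pool = ranked[:n_top]
                chosen = rng_program.choice(len(pool), size=n_par, replace=False)
                af = form_population(
                    np.stack(
                        [
                            _sample_plant_af(
                                pop_af[pool[c]],
                                founders.positions,
                                founders.chrom,
                                config.ld_decay,
                                rng_program,
                            )
                            for c in chosen
                        ]
                    )
                )
            else:
                af = found_from_founders(grp, n_par)
            pop_af[name] = af
            group_of[name] = grp
            sowing_year[name] = year
            is_check[name] = False
            names.append(name)
        year_members[year] = names

    populations = list(pop_af)
    af_full = np.stack([pop_af[p] for p in populations])

    # --- true breeding values (group-specific marker effects) ----------
    grp_arr = np.array([group_of[p] for p in populations])
    tbv = {}
    for s in SEASONS:
        vals = {
            g: 2.0 * af_full[:, qtl_biomass] @ beta_biomass[g][s] for g in ("A", "B")
        }
        tbv[f"biomass_{s}"] = np.where(grp_arr == "B", vals["B"], vals["A"])
    tbv["biomass_average"] = np.mean([tbv[f"biomass_{s}"] for s in SEASONS], axis=0)
    head_vals = {g: 2.0 * af_full[:, qtl_heading] @ beta_heading[g] for g in ("A", "B")}
    tbv["heading"] = np.where(grp_arr == "B", head_vals["B"], head_vals["A"])
    true_bv = pd.DataFrame(tbv, index=populations)
    # Calibrate the between-group trait difference to a modest, realistic
    # size (group_b_shift_sd genetic standard deviations) -- raw draws of
    # group-specific effects would otherwise separate the groups by many SDs.
    mask_b = grp_arr == "B"
    if mask_b.any() and (~mask_b).any():
        for col in true_bv.columns:
            a_vals = true_bv.loc[~mask_b, col]
            target = a_vals.mean() + config.group_b_shift_sd * a_vals.std()
            true_bv.loc[mask_b, col] += target - true_bv.loc[mask_b, col].mean()

    # --- trial structure and phenotypes --------------------------------
    rows = []
    trial_rows = []
    for year in range(1, config.n_years + 1):
        anchors = [name for name, lo, hi in chain if lo <= year <= hi]
        members = year_members[year]
        for t in range(config.n_trials_per_year):
            trial_id = f"Y{year:02d}T{t + 1}"
            trial_pops = members[t:: config.n_trials_per_year] + anchors
            trial_rows.append((trial_id, year, trial_pops))
            sowing = pd.Timestamp(year=2000 + year, month=4, day=1)
            schedule = _harvest_schedule(sowing)
            dates = [d for _, d in schedule]
            from poolgs.phenotypes import allocate_harvests_to_seasons

            seasons_of = allocate_harvests_to_seasons(dates, sowing)
            per_ps: dict[tuple[int, str], list[pd.Timestamp]] = {}
            for (py, d), s in zip(schedule, seasons_of):
                per_ps.setdefault((py, s), []).append(d)

            # biomass
            tbv_trial = true_bv.loc[trial_pops]
            for s in SEASONS:
                g = tbv_trial[f"biomass_{s}"].to_numpy()
                sg2 = max(float(np.var(g, ddof=1)), 1e-12)
                h2 = config.h2_by_season[s]
                n_rec = config.n_replicates * 2
                sigma_e = np.sqrt(n_rec * sg2 * (1.0 - h2) / h2) * config.residual_scale
                sigma_b = config.block_sd_scale * sigma_e
                mu = config.residual_scale * rng_pheno.normal(
                    0.0, config.trial_sd_scale * np.sqrt(sg2)
                )
                for b in range(config.n_replicates):
                    # block = physical field position: one effect per block
                    # and season, constant across the two production years
                    beff = rng_pheno.normal(0.0, sigma_b) if sigma_b > 0 else 0.0
                    for py in (1, 2):
                        harvests = per_ps.get((py, s), [])
                        if not harvests:
                            continue
                        eps = rng_pheno.normal(0.0, sigma_e, size=len(trial_pops)) if sigma_e > 0 else np.zeros(len(trial_pops))
                        v = mu + g + beff + eps
                        for pi, pop in enumerate(trial_pops):
                            for d in harvests:
                                rows.append(
                                    (
                                        pop,
                                        trial_id,
                                        year,
                                        py,
                                        d,
                                        f"{trial_id}_b{b + 1}",
                                        v[pi] / len(harvests),
                                        "biomass",
                                    )
                                )
            # heading-date-like trait: one score per row plot, one year
            g = tbv_trial["heading"].to_numpy()
            sg2 = max(float(np.var(g, ddof=1)), 1e-12)
            h2 = config.h2_heading
            sigma_e = np.sqrt(config.n_replicates * sg2 * (1.0 - h2) / h2) * config.residual_scale
            sigma_b = config.block_sd_scale * sigma_e
            mu = config.residual_scale * rng_pheno.normal(0.0, config.trial_sd_scale * np.sqrt(sg2))
            score_date = pd.Timestamp(year=2000 + year, month=11, day=1)
            for b in range(config.n_replicates):
                beff = rng_pheno.normal(0.0, sigma_b) if sigma_b > 0 else 0.0
                eps = rng_pheno.normal(0.0, sigma_e, size=len(trial_pops)) if sigma_e > 0 else np.zeros(len(trial_pops))
                v = 60.0 + mu + g + beff + eps
                for pi, pop in enumerate(trial_pops):
                    rows.append(
                        (pop, trial_id, year, 1, score_date, f"{trial_id}_b{b + 1}", v[pi], "heading")
                    )

    phenotypes = pd.DataFrame(
        rows,
        columns=[
            "population",
            "trial_id",
            "sowing_year",
            "production_year",
            "harvest_date",
            "block",
            "plot_value",
            "trait",
        ],
    )
    metadata = pd.DataFrame(
        {
            "population": populations,
            "group": [group_of[p] for p in populations],
            "sowing_year": [sowing_year[p] for p in populations],
            "is_check": [is_check[p] for p in populations],
        }
    )

    # --- genotyping ground truth and pooled reads ----------------------
    marker_ids = _locus_ids(founders.positions[marker_idx], founders.chrom[marker_idx], rng_reads)
    truth_afm = AlleleFrequencyMatrix(
        populations=populations, loci=marker_ids, af=af_full[:, marker_idx]
    )
    rcm = simulate_pool_reads(
        truth_afm,
        depth_mean=config.depth_mean,
        rng=rng_reads,
        pool_size=config.pool_size,
        dispersion=config.depth_dispersion,
    )
    truth = TruthSet(true_af=truth_afm, true_breeding_values=true_bv, group_of=group_of)
    return SimulationResult(
        truth=truth,
        read_counts=rcm,
        phenotypes=phenotypes,
        metadata=metadata,
        reference_chain=chain,
        config=config,
    )
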