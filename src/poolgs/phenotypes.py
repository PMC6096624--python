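"""Two-stage adjustment of multi-trial sward phenotypes.

Stage 1 analyses each trial (per season) as a randomised incomplete block
design by REML -- population fixed, block random -- giving each population an
adjusted mean (BLUE) and a weight equal to the inverse variance of that mean.
A companion fit with population random provides the variance components for
the line-mean heritability

    H2 = sigma2_population / (sigma2_population + sigma2_error / n_reps).

Adjusted means are then expressed relative to a chain of reference-check
cultivars: within every trial the era's anchor is set to zero, and offsets
between successive anchors are estimated from a weighted combined analysis
over their overlap era, so all values end up relative to the first anchor.
Stage 2 combines the scaled values over trials in a weighted one-way
random-effects model (population random, stage-1 weights as residual
precisions), yielding one adjusted phenotypic value and weight per
population and season.

Seasonal allocation of biomass harvests follows the five-season split of the
southern-hemisphere forage year: autumn (Mar-May), winter (Jun-Jul), early
spring (Aug-Sep), late spring (Oct-Nov), summer (Dec-Feb).  Each harvest's
growth window runs from the previous harvest (or sowing) and the harvest is
allocated to the season containing most days of that window.  Yield in the
first and second production year is treated as the same trait (repeated
records).  Heading date is recorded in days since 1 September and is not
season-split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from poolgs._reml import reml_fit

SEASON_MONTHS = {
    "autumn": (3, 4, 5),
    "winter": (6, 7),
    "early_spring": (8, 9),
    "late_spring": (10, 11),
    "summer": (12, 1, 2),
}
SEASONS = tuple(SEASON_MONTHS)
AVERAGE = "average"

_MONTH_TO_SEASON = {m: s for s, months in SEASON_MONTHS.items() for m in months}


class PhenotypeError(ValueError):
    pass


@dataclass
class VarianceComponents:
    sigma2_block: float
    sigma2_population: float
    sigma2_error: float
    n_effective_reps: float

    def __post_init__(self):
        for name in ("sigma2_block", "sigma2_population", "sigma2_error"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def season_of_month(month: int) -> str:
    return _MONTH_TO_SEASON[month]


def allocate_harvests_to_seasons(harvest_dates, sowing_date) -> list[str]:
    """Season label for each harvest based on its growth window.

    The window of the first harvest starts the day after sowing; later
    windows start the day after the previous harvest.  The harvest is
    assigned to the season with the most days in the window, ties broken
    toward the season containing the harvest date itself.
    """
    dates = [pd.Timestamp(d) for d in harvest_dates]
    if any(pd.isna(d) for d in dates):
        bad = [i for i, d in enumerate(dates) if pd.isna(d)]
        raise PhenotypeError(f"undated harvest records at positions {bad}")
    if sorted(dates) != dates:
        raise PhenotypeError("harvest dates must be ordered within a trial")
    prev = pd.Timestamp(sowing_date)
    labels = []
    for d in dates:
        window = pd.date_range(prev + pd.Timedelta(days=1), d, freq="D")
        counts: dict[str, int] = {}
        for day in window:
            s = season_of_month(day.month)
            counts[s] = counts.get(s, 0) + 1
        best = max(counts.values())
        winners = [s for s, c in counts.items() if c == best]
        if len(winners) == 1:
            labels.append(winners[0])
        else:
            harvest_season = season_of_month(d.month)
            labels.append(harvest_season if harvest_season in winners else winners[0])
        prev = d
    return labels


def seasonal_records(pheno: pd.DataFrame, trait: str = "biomass") -> pd.DataFrame:
    """Per-plot seasonal responses from raw harvest records.

    For biomass, each harvest is allocated to a season by its growth window
    and harvests within the same (plot, production year, season) are summed;
    an ``average`` season is added as the mean of the seasonal sums.  Heading
    records are single scores and pass through with season ``average``.

    Returns columns: population, trial_id, sowing_year, block,
    production_year, season, value.
    """
    df = pheno[pheno["trait"] == trait].copy()
    if df.empty:
        raise PhenotypeError(f"no records for trait {trait!r}")
    if trait != "biomass":
        out = df.rename(columns={"plot_value": "value"})
        out["season"] = AVERAGE
        return out[
            ["population", "trial_id", "sowing_year", "block", "production_year", "season", "value"]
        ].reset_index(drop=True)

    parts = []
    for trial_id, sub in df.groupby("trial_id", sort=False):
        sowing_year = int(sub["sowing_year"].iloc[0])
        sowing = pd.Timestamp(year=2000 + sowing_year, month=4, day=1)
        dates = sorted(pd.unique(sub["harvest_date"]))
        season_of = dict(zip(dates, allocate_harvests_to_seasons(dates, sowing)))
        sub = sub.assign(season=sub["harvest_date"].map(season_of))
        agg = (
            sub.groupby(["population", "block", "production_year", "season"], sort=False)[
                "plot_value"
            ]
            .sum()
            .reset_index()
            .rename(columns={"plot_value": "value"})
        )
        avg = (
            agg.groupby(["population", "block", "production_year"], sort=False)["value"]
            .mean()
            .reset_index()
            .assign(season=AVERAGE)
        )
        part = pd.concat([agg, avg], ignore_index=True)
        part["trial_id"] = trial_id
        part["sowing_year"] = sowing_year
        parts.append(part)
    return pd.concat(parts, ignore_index=True)[
        ["population", "trial_id", "sowing_year", "block", "production_year", "season", "value"]
    ]


def _designs(pops: pd.Series, blocks: pd.Series):
    pop_levels = list(pd.unique(pops))
    block_levels = list(pd.unique(blocks))
    X = (pops.to_numpy()[:, None] == np.array(pop_levels)[None, :]).astype(float)
    Z = (blocks.to_numpy()[:, None] == np.array(block_levels)[None, :]).astype(float)
    return pop_levels, block_levels, X, Z


def fit_within_trial(records: pd.DataFrame) -> tuple[pd.Series, pd.Series, VarianceComponents]:
    """Stage-1 REML fit of one trial-season: population fixed, block random.

    ``records`` needs columns population, block, value (seasonal responses,
    production years as repeated records).  Returns adjusted means, weights
    (inverse variance of each adjusted mean) and variance components; the
    population variance component comes from a companion fit with population
    random, for use in heritability estimation.
    """
    records = records.reset_index(drop=True)
    pops = records["population"].astype(str)
    blocks = records["block"].astype(str)
    y = records["value"].to_numpy(dtype=float)
    pop_levels, block_levels, X, Z = _designs(pops, blocks)
    if len(pop_levels) < 2:
        raise PhenotypeError("need at least 2 populations with data")
    if len(block_levels) < 2:
        raise PhenotypeError("need at least 2 blocks with data")
    counts = pd.crosstab(pops, blocks)
    if (counts.to_numpy().sum(axis=1) == 0).any():
        raise PhenotypeError("population without records")
    try:
        fit = reml_fit(y, X, {"block": Z})
    except np.linalg.LinAlgError as exc:
        raise PhenotypeError(
            f"confounded population/block layout in trial data: {exc}"
        ) from exc
    var_means = np.diag(fit.cov_beta)
    if np.any(var_means <= 0):
        var_means = np.maximum(var_means, 1e-12)
    means = pd.Series(fit.beta, index=pop_levels, name="adjusted_mean")
    weights = pd.Series(1.0 / var_means, index=pop_levels, name="weight")

    # companion fit: population random, for the genetic variance component
    ones = np.ones((len(y), 1))
    rfit = reml_fit(y, ones, {"population": X, "block": Z})
    vc = VarianceComponents(
        sigma2_block=fit.components["block"],
        sigma2_population=rfit.components["population"],
        sigma2_error=fit.sigma2_error,
        n_effective_reps=float(len(y)) / len(pop_levels),
    )
    return means, weights, vc


def estimate_heritability(vc: VarianceComponents, n_reps: float) -> float:
    """Line-mean heritability from within-trial variance components."""
    if n_reps < 1:
        raise PhenotypeError("n_reps must be >= 1")
    s2p, s2e = vc.sigma2_population, vc.sigma2_error
    if s2p == 0 and s2e == 0:
        raise PhenotypeError("heritability undefined: all variance components are zero")
    return float(np.clip(s2p / (s2p + s2e / n_reps), 0.0, 1.0))


def chain_scale_to_reference(
    stage1: pd.DataFrame, chain: list[tuple[str, int, int]]
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Scale per-trial adjusted means to the first anchor cultivar.

    ``stage1`` has columns population, trial_id, sowing_year, season, value,
    weight.  ``chain`` lists (anchor, first_year, last_year) eras in order; a
    trial belongs to the earliest era containing its sowing year.  Within
    each trial the era anchor's mean is subtracted; the offset of each later
    anchor relative to the first is estimated per season by a weighted
    combined analysis over the previous era's (already scaled) trials and
    added back, so every value is relative to anchor 1 (= 0).

    Returns the scaled table and per-season offsets/standard errors per
    anchor.
    """
    if not chain:
        raise PhenotypeError("reference chain is empty")
    stage1 = stage1.copy()

    def era_of(year: int) -> int:
        for i, (_, lo, hi) in enumerate(chain):
            if lo <= year <= hi:
                return i
        raise PhenotypeError(f"sowing year {year} not covered by any reference era")

    stage1["era"] = stage1["sowing_year"].astype(int).map(era_of)
    out_parts = []
    offsets: dict[str, dict[str, float]] = {chain[0][0]: {}}
    offset_se: dict[str, dict[str, float]] = {}
    for season, sub in stage1.groupby("season", sort=False):
        cum_offset = {0: 0.0}
        scaled_eras = []
        for i, (anchor, _, _) in enumerate(chain):
            era_df = sub[sub["era"] == i].copy()
            if i > 0:
                prev_scaled = scaled_eras[i - 1]
                prev_anchor = chain[i - 1][0]
                if anchor not in set(prev_scaled["population"]):
                    raise PhenotypeError(
                        f"broken reference chain: anchor {anchor!r} does not appear "
                        f"in the {prev_anchor!r} era trials (season {season!r})"
                    )
                combined = combine_across_trials(prev_scaled)
                off = float(combined.loc[combined["population"] == anchor, "value"].iloc[0])
                se = float(
                    np.sqrt(
                        1.0 / combined.loc[combined["population"] == anchor, "weight"].iloc[0]
                    )
                )
                cum_offset[i] = off
                offsets.setdefault(anchor, {})[season] = off
                offset_se.setdefault(anchor, {})[season] = se
            scaled_trials = []
            for trial_id, tdf in era_df.groupby("trial_id", sort=False):
                tdf = tdf.copy()
                at = tdf.loc[tdf["population"] == anchor, "value"]
                if at.empty:
                    raise PhenotypeError(
                        f"anchor {anchor!r} missing from trial {trial_id!r} (season {season!r})"
                    )
                tdf["value"] = tdf["value"] - float(at.iloc[0]) + cum_offset[i]
                scaled_trials.append(tdf)
            era_scaled = (
                pd.concat(scaled_trials, ignore_index=True)
                if scaled_trials
                else era_df.iloc[0:0]
            )
            scaled_eras.append(era_scaled)
        out_parts.append(pd.concat([e for e in scaled_eras if len(e)], ignore_index=True))
    scaled = pd.concat(out_parts, ignore_index=True).drop(columns=["era"])
    return scaled, {"offset": offsets, "se": offset_se}


def combine_across_trials(scaled: pd.DataFrame) -> pd.DataFrame:
    """Stage-2 weighted one-way random-effects combination (one season).

    Model: value_pt = g_p + e_pt with g ~ N(0, sigma2_g) and
    Var(e_pt) = 1 / weight_pt.  The stage-1 weights are absolute inverse
    variances of the adjusted means, so the residual variance is known and
    only the between-population variance is estimated (by marginal maximum
    likelihood; populations are independent given g, so the likelihood
    factorises).  No intercept is fitted: values are already relative to the
    anchor (= 0), so predictions shrink toward the anchor.  Returns the
    per-population prediction and its weight (inverse prediction error
    variance).
    """
    scaled = scaled.reset_index(drop=True)
    w = scaled["weight"].to_numpy(dtype=float)
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise PhenotypeError("stage-1 weights must be positive and finite")
    y = scaled["value"].to_numpy(dtype=float)
    pops = scaled["population"].astype(str)
    pop_levels = list(pd.unique(pops))
    codes = pops.map({p: i for i, p in enumerate(pop_levels)}).to_numpy()
    n_pop = len(pop_levels)
    sw = np.bincount(codes, weights=w, minlength=n_pop)
    swy = np.bincount(codes, weights=w * y, minlength=n_pop)
    swy2 = np.bincount(codes, weights=w * y * y, minlength=n_pop)
    means = swy / sw

    # Noise-free limit: every record equals its population mean.  Only
    # detectable when at least one population is replicated.
    counts = np.bincount(codes, minlength=n_pop)
    if counts.max() >= 2 and float(
        np.max(np.abs(y - means[codes]), initial=0.0)
    ) < 1e-10 * max(1.0, float(np.std(y))):
        return pd.DataFrame({"population": pop_levels, "value": means, "weight": sw})

    def neg_ll(log_s2g):
        s2g = np.exp(log_s2g)
        # per population: -2 lnL = ln|V_p| + y_p' V_p^-1 y_p (+ const) with
        # V_p = s2g J + diag(1/w); by Woodbury with known diagonal:
        # ln|V_p| = -sum(ln w) + ln(1 + s2g * sw_p)
        # quad    = sum(w y^2) - s2g * (sum w y)^2 / (1 + s2g * sw_p)
        denom = 1.0 + s2g * sw
        return float(np.sum(np.log(denom) + swy2 - s2g * swy ** 2 / denom))

    res = optimize.minimize_scalar(
        neg_ll, bounds=(-14.0, 14.0), method="bounded", options={"xatol": 1e-10}
    )
    s2g = float(np.exp(res.x))
    prec = sw + 1.0 / s2g
    blup = s2g * swy / (1.0 + s2g * sw)
    return pd.DataFrame({"population": pop_levels, "value": blup, "weight": prec})


@dataclass
class AdjustedPhenotypes:
    """Final adjusted phenotypic values and supporting per-trial results."""

    values: pd.DataFrame  # population, season, trait, value, weight
    stage1: pd.DataFrame  # population, trial_id, sowing_year, season, value, weight
    heritability: pd.DataFrame  # trial_id, sowing_year, season, h2, components
    offsets: dict


def adjust_phenotypes(
    pheno: pd.DataFrame,
    chain: list[tuple[str, int, int]],
    trait: str = "biomass",
) -> AdjustedPhenotypes:
    """Full two-stage pipeline for one trait.

    Raw harvest records -> seasonal plot responses -> within-trial adjusted
    means, weights and heritabilities -> chained scaling to the first anchor
    -> combined weighted prediction per population and season.
    """
    records = seasonal_records(pheno, trait=trait)
    stage1_rows = []
    h2_rows = []
    for (trial_id, season), sub in records.groupby(["trial_id", "season"], sort=False):
        means, weights, vc = fit_within_trial(sub)
        n_reps = vc.n_effective_reps
        try:
            h2 = estimate_heritability(vc, n_reps)
        except PhenotypeError:
            h2 = np.nan
        sowing_year = int(sub["sowing_year"].iloc[0])
        h2_rows.append(
            (
                trial_id,
                sowing_year,
                season,
                h2,
                vc.sigma2_population,
                vc.sigma2_block,
                vc.sigma2_error,
            )
        )
        for pop in means.index:
            stage1_rows.append(
                (pop, trial_id, sowing_year, season, means[pop], weights[pop])
            )
    stage1 = pd.DataFrame(
        stage1_rows,
        columns=["population", "trial_id", "sowing_year", "season", "value", "weight"],
    )
    heritability = pd.DataFrame(
        h2_rows,
        columns=[
            "trial_id",
            "sowing_year",
            "season",
            "h2",
            "sigma2_population",
            "sigma2_block",
            "sigma2_error",
        ],
    )
    scaled, offsets = chain_scale_to_reference(stage1, chain)
    value_parts = []
    for season, sub in scaled.groupby("season", sort=False):
        combined = combine_across_trials(sub)
        combined["season"] = season
        value_parts.append(combined)
    values = pd.concat(value_parts, ignore_index=True)
    values["trait"] = trait
    return AdjustedPhenotypes(
        values=values[["population", "season", "trait", "value", "weight"]],
        stage1=stage1,
        heritability=heritability,
        offsets=offsets,
    )
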