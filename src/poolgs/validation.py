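"""Forward (year-by-year) validation of genomic predictions.

Each prediction year is analysed with a reference population restricted to
populations trialled in earlier years: with a gap of ``g`` years, reference
populations are those sown in years <= year - g, and for biomass one extra
year is excluded (populations sown the year before the prediction year are
still being assessed in the field, so using them would leak contemporaneous
information).  Within each year the analysis can run globally or within
genetic groups: the reference + prediction subset is re-clustered on its own
genomic relationship matrix, clusters are mapped onto the global Group A/B
labels by majority overlap, 'unassigned' populations are dropped and a group
scope is skipped when its reference holds fewer than ``min_reference``
(default 50) populations.

For every year/scope/season: loci are variance-filtered on the reference,
priors elicited from the mean within-trial heritability of the reference
trials, a BayesA model fitted on the reference adjusted phenotypes (with
their weights), GEBVs predicted for the new populations, and accuracy
(Pearson correlation with adjusted phenotypes), a 10,000-resample bootstrap
summary and the bias slope (OLS of phenotype on GEBV; 1 = unbiased, > 1 =
under-prediction) reported, together with the moving average of accuracy
over the current and all prior years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from poolgs.bayesa import (
    BayesAError,
    elicit_priors,
    filter_by_reference_variance,
    fit_bayesa,
    predict_gebv,
)
from poolgs.genotyping import AlleleFrequencyMatrix
from poolgs.relationship import GroupAssignment, cluster_groups, compute_grm

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_REPS = 10000
DEFAULT_MIN_REFERENCE = 50


class ValidationError(ValueError):
    pass


@dataclass
class ForwardScheme:
    prediction_year: int
    gap_years: int
    trait: str
    scope: str
    reference_ids: list[str]
    prediction_ids: list[str]
    skipped: bool = False
    reason: str = ""


@dataclass
class BootstrapSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    reps: int


@dataclass
class ForwardDataset:
    """Inputs to forward validation for one trait.

    ``afm`` must be complete (imputed); ``adjusted`` holds the final
    adjusted phenotypic values (population, season, value, weight);
    ``trial_h2`` the within-trial heritabilities (trial_id, sowing_year,
    season, h2); ``metadata`` per-population sowing year and check status.
    """

    afm: AlleleFrequencyMatrix
    metadata: pd.DataFrame
    adjusted: pd.DataFrame
    trial_h2: pd.DataFrame
    global_assignment: GroupAssignment | None = None


@dataclass
class ValidationConfig:
    trait: str = "biomass"
    gap_years: int = 1
    scopes: tuple = ("global",)
    seasons: tuple | None = None
    n_iter: int = 12000
    n_burnin: int = 2000
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS
    min_reference: int = DEFAULT_MIN_REFERENCE
    min_reference_global: int = DEFAULT_MIN_REFERENCE
    variance_threshold: float = 0.01
    use_weights: bool = True
    fixed_k: int | None = None
    seed: int = 0


def reference_cutoff(prediction_year: int, gap_years: int, trait: str) -> int:
    """Last sowing year admitted to the reference population."""
    extra = 1 if trait == "biomass" else 0
    return prediction_year - gap_years - extra


def build_forward_scheme(
    metadata: pd.DataFrame,
    year: int,
    gap_years: int,
    trait: str,
    scope: str,
    afm: AlleleFrequencyMatrix | None = None,
    global_assignment: GroupAssignment | None = None,
    min_reference: int = DEFAULT_MIN_REFERENCE,
    min_reference_global: int = DEFAULT_MIN_REFERENCE,
    fixed_k: int | None = None,
) -> ForwardScheme:
    """Reference/prediction split for one year, trait and scope.

    Group scopes are skipped when the group-specific reference holds fewer
    than ``min_reference`` populations; the global scope likewise requires
    ``min_reference_global`` (the study design never predicted from very
    small references).
    """
    meta = metadata[~metadata["is_check"].astype(bool)]
    cutoff = reference_cutoff(year, gap_years, trait)
    ref = list(meta.loc[(meta["sowing_year"] >= 1) & (meta["sowing_year"] <= cutoff), "population"])
    pred = list(meta.loc[meta["sowing_year"] == year, "population"])
    scheme = ForwardScheme(
        prediction_year=year,
        gap_years=gap_years,
        trait=trait,
        scope=scope,
        reference_ids=ref,
        prediction_ids=pred,
    )
    if not pred:
        scheme.skipped, scheme.reason = True, "no prediction populations"
        return scheme
    if not ref:
        scheme.skipped, scheme.reason = True, "empty reference"
        return scheme
    if scope == "global":
        if len(ref) < min_reference_global:
            scheme.skipped = True
            scheme.reason = (
                f"global reference has {len(ref)} < {min_reference_global} populations"
            )
        return scheme
    if afm is None or global_assignment is None:
        raise ValidationError("group scopes require the AF matrix and a global assignment")
    subset = ref + pred
    idx = afm.population_index(subset)
    grm = compute_grm(afm.af[idx], populations=subset)
    assignment = cluster_groups(grm, reference=global_assignment, fixed_k=fixed_k)
    scheme.reference_ids = [p for p in ref if assignment.labels.get(p) == scope]
    scheme.prediction_ids = [p for p in pred if assignment.labels.get(p) == scope]
    if len(scheme.reference_ids) < min_reference:
        scheme.skipped = True
        scheme.reason = (
            f"group {scope} reference has {len(scheme.reference_ids)} < {min_reference} populations"
        )
    elif not scheme.prediction_ids:
        scheme.skipped, scheme.reason = True, f"no group-{scope} prediction populations"
    return scheme


def _reference_artifacts(dataset: ForwardDataset, config: ValidationConfig, scheme: ForwardScheme):
    """Everything estimated from the reference side only: retained loci,
    reference heritability, and per-season (y, X, weights, priors).

    Kept separate so a leakage audit can verify these are untouched by any
    change to prediction-year phenotypes.
    """
    afm = dataset.afm
    retained = filter_by_reference_variance(
        afm, scheme.reference_ids, threshold=config.variance_threshold
    )
    cutoff = reference_cutoff(scheme.prediction_year, scheme.gap_years, scheme.trait)
    h2_rows = dataset.trial_h2[
        (dataset.trial_h2["sowing_year"] >= 1) & (dataset.trial_h2["sowing_year"] <= cutoff)
    ]
    h2 = float(np.nanmean(h2_rows["h2"])) if len(h2_rows) else np.nan
    h2 = float(np.clip(h2, 0.01, 0.99))
    adj = dataset.adjusted
    seasons = (
        list(config.seasons)
        if config.seasons is not None
        else list(pd.unique(adj["season"]))
    )
    per_season = {}
    ref_index = afm.population_index(scheme.reference_ids)
    X_ref_all = 2.0 * afm.af[np.ix_(ref_index, retained)]
    ref_pos = {p: i for i, p in enumerate(scheme.reference_ids)}
    for season in seasons:
        sub = adj[(adj["season"] == season) & (adj["population"].isin(ref_pos))]
        if len(sub) < 3:
            continue
        rows = np.array([ref_pos[p] for p in sub["population"]])
        y = sub["value"].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float) if config.use_weights else None
        X = X_ref_all[rows]
        try:
            priors = elicit_priors(y, X, h2)
        except BayesAError as exc:
            logger.warning(
                "year %s scope %s season %s: %s", scheme.prediction_year, scheme.scope, season, exc
            )
            continue
        per_season[season] = {"y": y, "X": X, "weights": w, "priors": priors}
    return {"retained": retained, "h2": h2, "per_season": per_season}


def bootstrap_accuracy(
    gebv, pheno, reps: int = DEFAULT_BOOTSTRAP_REPS, seed: int = 0, max_redraws: int = 100
) -> BootstrapSummary:
    """Bootstrap the GEBV-phenotype correlation by resampling pairs.

    Degenerate resamples (zero variance on either side) are redrawn rather
    than scored, to avoid undefined correlations.
    """
    gebv = np.asarray(gebv, dtype=float)
    pheno = np.asarray(pheno, dtype=float)
    n = gebv.shape[0]
    if n < 3 or pheno.shape[0] != n:
        raise ValidationError(f"need >= 3 paired records, got {n}")
    rng = np.random.default_rng(seed)

    def corr_rows(idx):
        g = gebv[idx]
        p = pheno[idx]
        gc = g - g.mean(axis=1, keepdims=True)
        pc = p - p.mean(axis=1, keepdims=True)
        sg = np.sqrt((gc ** 2).sum(axis=1))
        sp = np.sqrt((pc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (gc * pc).sum(axis=1) / (sg * sp)
        return r

    idx = rng.integers(0, n, size=(reps, n))
    r = corr_rows(idx)
    for _ in range(max_redraws):
        bad = ~np.isfinite(r)
        if not bad.any():
            break
        idx_new = rng.integers(0, n, size=(int(bad.sum()), n))
        r[bad] = corr_rows(idx_new)
    else:
        raise ValidationError("could not draw non-degenerate bootstrap resamples")
    lo, hi = np.percentile(r, [2.5, 97.5])
    return BootstrapSummary(
        mean=float(r.mean()), sd=float(r.std(ddof=1)), ci_low=float(lo), ci_high=float(hi), reps=reps
    )


def bias_slope(pheno, gebv) -> float:
    """OLS slope of adjusted phenotype on GEBV (1 = unbiased, > 1 =
    under-prediction of differences)."""
    pheno = np.asarray(pheno, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    vg = gebv.var()
    if vg <= 0:
        raise ValidationError("GEBV variance is zero; bias slope undefined")
    return float(np.cov(pheno, gebv, ddof=0)[0, 1] / vg)


@dataclass
class ValidationRun:
    results: pd.DataFrame
    schemes: list[ForwardScheme] = field(default_factory=list)


def run_forward_validation(dataset: ForwardDataset, config: ValidationConfig) -> ValidationRun:
    """Cycle forward prediction across years and scopes for one trait."""
    meta = dataset.metadata[~dataset.metadata["is_check"].astype(bool)]
    years = sorted(meta["sowing_year"].unique())
    if len(years) < 2:
        raise ValidationError("forward validation needs at least 2 sowing years")
    if any(s != "global" for s in config.scopes) and dataset.global_assignment is None:
        raise ValidationError("group scopes require dataset.global_assignment")

    rows = []
    schemes = []
    for year in years:
        if reference_cutoff(year, config.gap_years, config.trait) < years[0]:
            continue
        for scope in config.scopes:
            scheme = build_forward_scheme(
                dataset.metadata,
                year,
                config.gap_years,
                config.trait,
                scope,
                afm=dataset.afm,
                global_assignment=dataset.global_assignment,
                min_reference=config.min_reference,
                min_reference_global=config.min_reference_global,
                fixed_k=config.fixed_k,
            )
            schemes.append(scheme)
            if scheme.skipped:
                logger.info("year %s scope %s skipped: %s", year, scope, scheme.reason)
                continue
            arts = _reference_artifacts(dataset, config, scheme)
            pred_index = dataset.afm.population_index(scheme.prediction_ids)
            X_pred_all = 2.0 * dataset.afm.af[np.ix_(pred_index, arts["retained"])]
            pred_pos = {p: i for i, p in enumerate(scheme.prediction_ids)}
            for si, (season, parts) in enumerate(arts["per_season"].items()):
                scope_code = {"global": 0, "A": 1, "B": 2}.get(scope, 3)
                ss = np.random.SeedSequence([config.seed, int(year), scope_code, si])
                chain_seed = int(ss.generate_state(1)[0] % (2 ** 31))
                model = fit_bayesa(
                    parts["y"],
                    parts["X"],
                    parts["priors"],
                    n_iter=config.n_iter,
                    n_burnin=config.n_burnin,
                    seed=chain_seed,
                    weights=parts["weights"],
                )
                obs = dataset.adjusted[
                    (dataset.adjusted["season"] == season)
                    & (dataset.adjusted["population"].isin(pred_pos))
                ]
                if len(obs) < 3:
                    continue
                rows_idx = np.array([pred_pos[p] for p in obs["population"]])
                gebv = predict_gebv(model, X_pred_all[rows_idx])
                pheno = obs["value"].to_numpy(dtype=float)
                if np.std(gebv) == 0 or np.std(pheno) == 0:
                    continue
                acc = float(np.corrcoef(gebv, pheno)[0, 1])
                boot = bootstrap_accuracy(
                    gebv, pheno, reps=config.bootstrap_reps, seed=chain_seed
                )
                slope = bias_slope(pheno, gebv)
                rows.append(
                    {
                        "prediction_year": year,
                        "scope": scope,
                        "season": season,
                        "trait": config.trait,
                        "n_reference": len(scheme.reference_ids),
                        "n_prediction": len(obs),
                        "h2_prior": arts["h2"],
                        "accuracy": acc,
                        "boot_mean": boot.mean,
                        "boot_sd": boot.sd,
                        "ci_low": boot.ci_low,
                        "ci_high": boot.ci_high,
                        "bias_slope": slope,
                    }
                )
    results = pd.DataFrame(rows)
    if len(results):
        results = results.sort_values(["scope", "season", "prediction_year"]).reset_index(drop=True)
        results["moving_average"] = results.groupby(["scope", "season"])["accuracy"].transform(
            lambda s: s.expanding().mean()
        )
    return ValidationRun(results=results, schemes=schemes)


def accuracy_table(run: ValidationRun, scope: str = "global") -> pd.DataFrame:
    """Year x season accuracy table with mean/SD footer rows."""
    res = run.results[run.results["scope"] == scope]
    table = res.pivot_table(index="prediction_year", columns="season", values="accuracy")
    table.loc["Mean"] = table.mean()
    table.loc["SD"] = table.iloc[:-1].std()
    return table
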