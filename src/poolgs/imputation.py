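"""LD-kNN imputation of missing allele frequencies.

The classical LD-kNN genotype imputation picks, for each target locus, the
``l`` loci in strongest linkage disequilibrium with it, measures distances
between samples over those loci only, and fills the missing call from the
``k`` nearest samples.  Pool-seq data carry continuous allele frequencies
rather than genotype classes, so this implementation generalises the method:

- LD is the squared Pearson correlation of allele frequencies across
  populations observed at both loci (pairs with fewer than
  ``min_shared_obs`` shared observations are excluded from ranking);
- distance between populations is the mean absolute allele-frequency
  difference over the ``l`` selected loci (missing coordinates skipped);
- the imputed value is the inverse-distance-weighted mean of the observed
  frequencies at the target locus among the ``k`` nearest populations.

Observed entries are never modified, imputed values are convex combinations
of observed values at the same locus (except in the stated fallbacks), and
ties are broken by stable input order throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from poolgs.genotyping import AlleleFrequencyMatrix

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


@dataclass
class ImputationParams:
    k_neighbours: int = 11
    l_ld_loci: int = 17
    min_shared_obs: int = 5
    epsilon: float = 1e-8

    def validate(self):
        if self.k_neighbours < 1:
            raise ImputationError("k_neighbours must be >= 1")
        if self.l_ld_loci < 1:
            raise ImputationError("l_ld_loci must be >= 1")


def _masked_corr_with_target(af: np.ndarray, obs: np.ndarray, target: int, min_shared: int):
    """Pearson r^2 of the target column with every column, over shared
    non-missing populations; columns with too few shared observations get NaN."""
    t = np.where(obs[:, target], af[:, target], 0.0)
    ot = obs[:, target].astype(float)
    af0 = np.where(obs, af, 0.0)
    obs_f = obs.astype(float)

    n = obs_f.T @ ot
    sx = af0.T @ ot
    sy = obs_f.T @ t
    sxy = af0.T @ t
    sxx = (af0 ** 2).T @ ot
    syy = obs_f.T @ (t ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx ** 2 / n
        vy = syy - sy ** 2 / n
        r2 = cov ** 2 / (vx * vy)
    r2[(n < min_shared)] = np.nan
    r2[~np.isfinite(r2)] = np.nan
    return r2


def rank_ld_loci(
    afm: AlleleFrequencyMatrix,
    target_locus: int | str,
    l: int,
    min_shared_obs: int = 5,
) -> np.ndarray:
    """Indices of the ``l`` loci in strongest LD (r^2) with the target locus.

    Ties are broken by locus order.  Loci sharing fewer than
    ``min_shared_obs`` observed populations with the target are excluded; if
    fewer than ``l`` candidates remain, all of them are returned.
    """
    if isinstance(target_locus, str):
        target = afm.loci.index(target_locus)
    else:
        target = int(target_locus)
    obs = ~afm.missing
    if not obs[:, target].any():
        raise ImputationError(f"target locus {afm.loci[target]!r} is entirely missing")
    r2 = _masked_corr_with_target(afm.af, obs, target, min_shared_obs)
    r2[target] = np.nan
    candidates = np.flatnonzero(~np.isnan(r2))
    order = candidates[np.argsort(-r2[candidates], kind="stable")]
    return order[:l]


def _impute_entry(af, obs, p, j, ld_idx, k, eps):
    """Inverse-distance-weighted kNN value for entry (p, j); None if no donor."""
    donors = np.flatnonzero(obs[:, j])
    donors = donors[donors != p]
    if donors.size == 0:
        return None
    sub = af[:, ld_idx]
    sub_obs = obs[:, ld_idx]
    shared = sub_obs[p] & sub_obs[donors]
    n_used = shared.sum(axis=1)
    diff = np.abs(np.where(shared, sub[donors] - sub[p], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = diff.sum(axis=1) / n_used
    # donors sharing no informative coordinate are pushed to the back
    dist[n_used == 0] = np.inf
    order = np.argsort(dist, kind="stable")[: min(k, donors.size)]
    chosen = donors[order]
    d = dist[order]
    d = np.where(np.isfinite(d), d, 1.0)  # uninformative donors: unit distance
    w = 1.0 / np.maximum(d, eps)
    return float(np.sum(w * af[chosen, j]) / np.sum(w))


def impute_ldknni(
    afm: AlleleFrequencyMatrix,
    params: ImputationParams | None = None,
    seed: int = 0,
) -> AlleleFrequencyMatrix:
    """Impute every missing allele frequency by LD-kNN.

    LD ranking, distances and donors are all computed from the original
    observed entries (imputed values are never reused as donors).  Fallbacks:
    fewer than ``k`` donors -> use all available; a locus with no observed
    value at all -> the population's mean over its own observed loci, else
    the global observed mean.  The procedure is deterministic; ``seed`` is
    accepted for interface symmetry.
    """
    params = params or ImputationParams()
    params.validate()
    out = afm.copy()
    obs = ~afm.missing
    if obs.all():
        return out
    if not obs.any():
        raise ImputationError("allele-frequency matrix has no observed entries")
    global_mean = float(np.nanmean(afm.af))
    row_means = np.nanmean(np.where(obs, afm.af, np.nan), axis=1)

    missing_cols = np.flatnonzero((~obs).any(axis=0))
    for j in missing_cols:
        rows = np.flatnonzero(~obs[:, j])
        if not obs[:, j].any():
            for p in rows:
                val = row_means[p] if np.isfinite(row_means[p]) else global_mean
                out.af[p, j] = val
                out.imputed[p, j] = True
            continue
        ld_idx = rank_ld_loci(afm, j, params.l_ld_loci, params.min_shared_obs)
        if ld_idx.size == 0:
            ld_idx = np.array([j])
        for p in rows:
            val = _impute_entry(afm.af, obs, p, j, ld_idx, params.k_neighbours, params.epsilon)
            if val is None:
                val = row_means[p] if np.isfinite(row_means[p]) else global_mean
            out.af[p, j] = min(1.0, max(0.0, val))
            out.imputed[p, j] = True
    return out


def assess_imputation(
    afm_complete: AlleleFrequencyMatrix,
    mask_fraction: float,
    params: ImputationParams | None = None,
    seed: int = 0,
    max_attempts: int = 100,
) -> float:
    """Imputation accuracy by masking known entries.

    Masks ``mask_fraction`` of the entries uniformly at random (redrawing up
    to ``max_attempts`` times if a locus would lose all its observations),
    imputes, and returns the Pearson correlation between the true and
    imputed values over the masked entries.
    """
    if not (0.0 < mask_fraction < 1.0):
        raise ImputationError("mask_fraction must be in (0, 1)")
    if afm_complete.n_missing:
        raise ImputationError("assess_imputation requires a complete matrix")
    rng = np.random.default_rng(seed)
    P, M = afm_complete.af.shape
    n_mask = max(1, int(round(mask_fraction * P * M)))
    for _ in range(max_attempts):
        flat = rng.choice(P * M, size=n_mask, replace=False)
        mask = np.zeros(P * M, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(P, M)
        if not mask.all(axis=0).any():
            break
    else:
        raise ImputationError(
            f"could not draw a mask without fully-missing loci in {max_attempts} attempts"
        )
    masked = afm_complete.copy()
    masked.af[mask] = np.nan
    imputed = impute_ldknni(masked, params=params, seed=seed)
    truth = afm_complete.af[mask]
    est = imputed.af[mask]
    return float(np.corrcoef(truth, est)[0, 1])
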