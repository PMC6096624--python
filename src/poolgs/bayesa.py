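"""BayesA whole-genome regression for continuous 0-2 genotype codes.

The model is

    y = u 1_n + X v + e,  v_i ~ N(0, sigma2_v_i),  e ~ N(0, sigma2_e W^{-1})

where X holds mean-centred genotype codes (twice the pool reference-allele
frequency), every marker carries its own variance with a scaled-inverse-
chi-square prior, and optional per-record weights from the phenotype stage
enter as residual precision multipliers.  Prior scales are elicited from a
trait heritability: the marker-variance scale is set so the implied total
marker variance matches h2 * var(y) and the residual scale so the residual
prior mode matches (1 - h2) * var(y), with default 5 degrees of freedom.

Inference is single-site Gibbs sampling with a running residual (O(nm) per
sweep), compiled with numba.  Full conditionals:

- u  ~ N( sum(w e*) / sum(w), sigma2_e / sum(w) )            (e* = e + u 1)
- v_i ~ N( rhs / C, sigma2_e / C ),  C = sum w x^2 + sigma2_e / sigma2_v_i
- sigma2_v_i ~ (nu_v S_v + v_i^2) / chi2(nu_v + 1)
- sigma2_e   ~ (nu_e S_e + sum w e^2) / chi2(nu_e + n)

Posterior means over post-burn-in samples define the fitted model; genomic
estimated breeding values are u + X_centred v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

DEFAULT_NU = 5.0
DEFAULT_N_ITER = 12000
DEFAULT_N_BURNIN = 2000


class BayesAError(ValueError):
    pass


@dataclass
class BayesAPriors:
    nu_v: float
    S_v: float
    nu_e: float
    S_e: float


@dataclass
class BayesAModel:
    u: float
    v: np.ndarray
    sigma2_v: np.ndarray
    sigma2_e: float
    priors: BayesAPriors
    column_means: np.ndarray
    locus_ids: list[str] | None
    n_iter: int
    n_burnin: int
    seed: int
    sigma2_e_trace: np.ndarray


def filter_by_reference_variance(afm, reference_ids, threshold: float = 0.01) -> np.ndarray:
    """Indices of loci whose AF variance across the reference populations is
    strictly above ``threshold``.

    Applied at every forward-validation iteration on that iteration's
    reference set, so the marker panel never uses prediction-set information.
    """
    if len(reference_ids) == 0:
        raise BayesAError("reference_ids must be non-empty")
    idx = afm.population_index(reference_ids)
    sub = afm.af[idx]
    if np.isnan(sub).any():
        raise BayesAError("variance filter requires complete (imputed) frequencies")
    var = sub.var(axis=0)
    keep = np.flatnonzero(var > threshold)
    if keep.size == 0:
        raise BayesAError("no loci retained by the reference variance filter")
    return keep


def elicit_priors(y, X, h2: float, nu: float = DEFAULT_NU) -> BayesAPriors:
    """Heritability-based scaled-inverse-chi-square prior scales.

    S_v = var(y) * h2 * (nu + 2) / sum_j var(X_j) and
    S_e = var(y) * (1 - h2) * (nu + 2), with nu_v = nu_e = nu.
    """
    if not (0.0 < h2 < 1.0):
        raise BayesAError(f"h2 must be in (0, 1), got {h2}")
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise BayesAError("X must be non-empty")
    vary = float(np.var(np.asarray(y, dtype=float), ddof=1))
    if not np.isfinite(vary) or vary <= 0:
        raise BayesAError("response variance is degenerate")
    sum_vx = float(np.sum(X.var(axis=0)))
    if sum_vx <= 0:
        raise BayesAError("all marker columns are constant")
    S_v = vary * h2 * (nu + 2.0) / sum_vx
    S_e = vary * (1.0 - h2) * (nu + 2.0)
    return BayesAPriors(nu_v=nu, S_v=S_v, nu_e=nu, S_e=S_e)


@njit(cache=True)
def _gibbs(y, X, w, nu_v, S_v, nu_e, S_e, n_iter, n_burnin, seed):
    np.random.seed(seed)
    n, m = X.shape
    wxx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        wxx[j] = s
    sw = np.sum(w)

    v = np.zeros(m)
    s2v = np.full(m, max(S_v, 1e-10))
    u = np.sum(w * y) / sw
    e = y - u
    s2e = max(S_e, 1e-8 * (np.var(y) + 1e-12))

    u_acc = 0.0
    v_acc = np.zeros(m)
    s2v_acc = np.zeros(m)
    s2e_acc = 0.0
    trace = np.empty(n_iter)
    n_post = 0
    for it in range(n_iter):
        # intercept
        mean_u = u + np.sum(w * e) / sw
        new_u = mean_u + np.random.normal() * np.sqrt(s2e / sw)
        delta = new_u - u
        for i in range(n):
            e[i] -= delta
        u = new_u
        # marker effects and their variances
        for j in range(m):
            rhs = wxx[j] * v[j]
            for i in range(n):
                rhs += w[i] * X[i, j] * e[i]
            C = wxx[j] + s2e / s2v[j]
            mu = rhs / C
            new_v = mu + np.random.normal() * np.sqrt(s2e / C)
            dv = new_v - v[j]
            if dv != 0.0:
                for i in range(n):
                    e[i] -= X[i, j] * dv
            v[j] = new_v
            s2v[j] = (nu_v * S_v + v[j] * v[j]) / np.random.chisquare(nu_v + 1.0)
        # residual variance
        sse = 0.0
        for i in range(n):
            sse += w[i] * e[i] * e[i]
        s2e = (nu_e * S_e + sse) / np.random.chisquare(nu_e + n)
        trace[it] = s2e
        if it >= n_burnin:
            n_post += 1
            u_acc += u
            for j in range(m):
                v_acc[j] += v[j]
                s2v_acc[j] += s2v[j]
            s2e_acc += s2e
    return (
        u_acc / n_post,
        v_acc / n_post,
        s2v_acc / n_post,
        s2e_acc / n_post,
        trace,
    )


def fit_bayesa(
    y,
    X,
    priors: BayesAPriors,
    n_iter: int = DEFAULT_N_ITER,
    n_burnin: int = DEFAULT_N_BURNIN,
    seed: int = 0,
    weights=None,
    locus_ids: list[str] | None = None,
) -> BayesAModel:
    """Fit BayesA by Gibbs sampling and return posterior means.

    ``X`` holds genotype codes in [0, 2]; columns are mean-centred
    internally and the centring constants stored for prediction.  Identical
    seeds give identical chains.
    """
    y = np.ascontiguousarray(y, dtype=float)
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise BayesAError(f"shape mismatch: X {X.shape} vs y {y.shape}")
    if not (0 <= n_burnin < n_iter):
        raise BayesAError(f"need 0 <= n_burnin < n_iter, got {n_burnin} >= {n_iter}")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.ascontiguousarray(weights, dtype=float)
        if np.any(w <= 0) or w.shape != y.shape:
            raise BayesAError("weights must be positive and match y")
        w = w * (len(w) / w.sum())  # normalise so sigma2_e keeps the trait scale
    column_means = X.mean(axis=0)
    Xc = X - column_means
    u, v, s2v, s2e, trace = _gibbs(
        y,
        Xc,
        w,
        float(priors.nu_v),
        float(priors.S_v),
        float(priors.nu_e),
        float(priors.S_e),
        int(n_iter),
        int(n_burnin),
        int(seed) % (2 ** 31),
    )
    if not np.all(np.isfinite(trace)):
        bad = int(np.flatnonzero(~np.isfinite(trace))[0])
        raise BayesAError(f"non-finite residual variance at iteration {bad}")
    if not (np.isfinite(u) and np.all(np.isfinite(v))):
        raise BayesAError("non-finite posterior means")
    return BayesAModel(
        u=float(u),
        v=v,
        sigma2_v=s2v,
        sigma2_e=float(s2e),
        priors=priors,
        column_means=column_means,
        locus_ids=list(locus_ids) if locus_ids is not None else None,
        n_iter=n_iter,
        n_burnin=n_burnin,
        seed=seed,
        sigma2_e_trace=trace,
    )


def predict_gebv(model: BayesAModel, X_new, locus_ids: list[str] | None = None) -> np.ndarray:
    """Genomic estimated breeding values for new genotype codes.

    Columns must match the model's retained loci and are centred with the
    model's stored column means.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.v.shape[0]:
        raise BayesAError(
            f"locus-set mismatch: model has {model.v.shape[0]} loci, X_new has {X_new.shape[1]}"
        )
    if locus_ids is not None and model.locus_ids is not None:
        if list(locus_ids) != list(model.locus_ids):
            missing = sorted(set(model.locus_ids) - set(locus_ids))
            raise BayesAError(f"locus-set mismatch; missing loci: {missing[:10]}")
    return model.u + (X_new - model.column_means) @ model.v


def geweke_z(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke stationarity z-score comparing early and late chain segments."""
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    a = trace[: int(first * n)]
    b = trace[int((1.0 - last) * n):]

    def spectral_var(x):
        x = x - x.mean()
        # batch-means estimate of the long-run variance
        nb = max(1, int(np.sqrt(x.size)))
        k = x.size // nb
        if k < 2:
            return x.var(ddof=1) / x.size
        means = x[: nb * k].reshape(k, nb).mean(axis=1)
        return means.var(ddof=1) / k

    return float((a.mean() - b.mean()) / np.sqrt(spectral_var(a) + spectral_var(b)))
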