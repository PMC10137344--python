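"""Comparator selection criteria: GBLUP and BayesB.

GBLUP solves the single-trait animal-model mixed-model equations with a
VanRaden (method 1) genomic relationship matrix and the variance ratio
treated as known from the heritability.  BayesB is a Gibbs sampler over
marker effects with a point mass at zero (probability ``pi``) and
marker-specific variances under a scaled-inverse-chi-squared prior; its
inner loop is compiled with numba because the per-marker updates are
inherently sequential.

Both estimators return breeding values on the same footing the simulator
uses to select parents, so they can be swapped in for the kinship-index
criterion inside the breeding program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .exceptions import ConfigurationError, DegenerateDataError, NumericalError

__all__ = ["GRM", "MarkerEffectPosterior", "grm_vanraden", "gblup_ebv", "bayesb_ebv"]


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    """Genomic relationship matrix with the frequencies used for centring."""

    G: np.ndarray
    reference_freqs: np.ndarray
    marker_mask: np.ndarray  # markers actually used (polymorphic)


def grm_vanraden(Z: np.ndarray, freqs: np.ndarray | None = None) -> GRM:
    """VanRaden method-1 GRM: ``G = W W' / (2 sum p(1-p))``, ``W = Z - 2p``.

    ``freqs`` defaults to the allele frequencies observed in ``Z`` itself;
    monomorphic markers (p in {0, 1}) are excluded from the computation.
    """
    Z = np.asarray(Z, dtype=float)
    if freqs is None:
        freqs = Z.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs > 0) & (freqs < 1)
    if not mask.any():
        raise DegenerateDataError("all markers are monomorphic; GRM undefined")
    p = freqs[mask]
    W = Z[:, mask] - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return GRM(G=(W @ W.T) / denom, reference_freqs=freqs, marker_mask=mask)


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------


def gblup_ebv(
    y: np.ndarray,
    G: GRM | np.ndarray,
    h2: float,
    ridge: float = 0.01,
) -> np.ndarray:
    """Animal-model GBLUP breeding values with known variance ratio.

    ``y`` may contain NaN for candidates without phenotypes; those
    individuals still receive EBVs through their genomic relationships.
    The model has an overall mean as the only fixed effect and
    ``lambda = (1 - h2) / h2``.  ``ridge`` is added to the diagonal of G
    before inversion to guarantee positive definiteness.
    """
    if not (0 < h2 < 1):
        raise ConfigurationError("GBLUP needs heritability strictly in (0, 1)")
    Gm = G.G if isinstance(G, GRM) else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Gm.shape != (n, n):
        raise ConfigurationError("G must be n x n for the n candidates/records")
    obs = np.isfinite(y)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ConfigurationError("no phenotyped individuals to train on")
    lam = (1.0 - h2) / h2
    try:
        Ginv = np.linalg.inv(Gm + ridge * np.eye(n))
        # MME: [[1'1, 1'Z], [Z'1, Z'Z + lam * Ginv]] [mu; g] = [1'y; Z'y]
        # with Z the 0/1 incidence of observed records on animals.
        zz = np.diag(obs.astype(float))
        lhs = np.empty((n + 1, n + 1))
        lhs[0, 0] = n_obs
        lhs[0, 1:] = obs
        lhs[1:, 0] = obs
        lhs[1:, 1:] = zz + lam * Ginv
        rhs = np.empty(n + 1)
        rhs[0] = y[obs].sum()
        rhs[1:] = np.where(obs, np.nan_to_num(y), 0.0)
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"mixed-model equations singular (n={n}, n_obs={n_obs}, "
            f"lambda={lam:.3g}, ridge={ridge:g}): {exc}"
        ) from exc
    return sol[1:]


# ---------------------------------------------------------------------------
# BayesB
# ---------------------------------------------------------------------------


@dataclass
class MarkerEffectPosterior:
    """Posterior summaries of BayesB marker effects."""

    mean_effects: np.ndarray
    inclusion_prob: np.ndarray
    settings: dict

    def __post_init__(self):
        if not np.all(np.isfinite(self.mean_effects)):
            raise NumericalError("non-finite posterior mean marker effects")


@njit(cache=True)
def _bayesb_gibbs(
    W,            # (n, m) column-centred genotype matrix, Fortran order
    y,            # (n,) centred phenotypes
    pi,           # prior exclusion probability
    n_iter, n_burn,
    nu, S,        # marker-variance prior df and scale
    nu_e, Se,     # residual-variance prior df and scale
    update_marker_var, update_resid_var,
    sigma2_init, sigma2e_init,
    seed,
):
    np.random.seed(seed)
    n, m = W.shape
    alpha = np.zeros(m)
    delta = np.zeros(m)
    sigma2 = np.full(m, sigma2_init)
    sigma2e = sigma2e_init
    e = y.copy()
    css = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        css[j] = s
    alpha_sum = np.zeros(m)
    delta_sum = np.zeros(m)
    kept = 0
    log_prior_odds = np.log((1.0 - pi) / pi) if pi > 0.0 else 0.0
    for it in range(n_iter):
        for j in range(m):
            c = css[j]
            if c <= 0.0:
                continue
            old = alpha[j]
            r = old * c
            for i in range(n):
                r += W[i, j] * e[i]
            s2j = sigma2[j]
            if pi > 0.0:
                v0 = c * sigma2e
                v1 = v0 + c * c * s2j
                logr = (
                    0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
                    + log_prior_odds
                )
                if logr > 35.0:
                    p1 = 1.0
                elif logr < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-logr))
                include = np.random.random() < p1
            else:
                include = True
            if include:
                prec = c / sigma2e + 1.0 / s2j
                mean = (r / sigma2e) / prec
                a = mean + np.random.normal() / np.sqrt(prec)
                delta[j] = 1.0
            else:
                a = 0.0
                delta[j] = 0.0
            if a != old:
                diff = old - a
                for i in range(n):
                    e[i] += W[i, j] * diff
            alpha[j] = a
            if update_marker_var:
                sigma2[j] = (nu * S + a * a * delta[j]) / np.random.chisquare(
                    nu + delta[j]
                )
        if update_resid_var:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma2e = (sse + nu_e * Se) / np.random.chisquare(n + nu_e)
        if it >= n_burn:
            kept += 1
            for j in range(m):
                alpha_sum[j] += alpha[j]
                delta_sum[j] += delta[j]
    return alpha_sum / kept, delta_sum / kept


def bayesb_ebv(
    y: np.ndarray,
    Z: np.ndarray,
    pi: float = 0.95,
    n_iter: int = 2000,
    n_burn: int = 500,
    seed: int = 0,
    h2: float = 0.5,
    df: float = 4.234,
    scale: float | None = None,
    fixed_marker_variance: float | None = None,
    fixed_residual_variance: float | None = None,
) -> tuple[np.ndarray, MarkerEffectPosterior]:
    """BayesB breeding values via Gibbs sampling over marker effects.

    Each marker effect is zero with probability ``pi`` and otherwise normal
    with a marker-specific variance under a scaled-inverse-chi-squared
    (``df``, ``scale``) prior; the default prior scale is derived from
    ``h2`` and the observed marker heterozygosity so the implied genetic
    variance matches ``h2 * var(y)``.  Rows of ``y`` may be NaN (candidates
    without records); EBVs are returned for every row of ``Z`` as
    ``W @ posterior-mean effects`` with ``W`` the column-centred genotypes.

    Setting ``fixed_marker_variance`` (with ``pi=0``) collapses the model
    to SNP-BLUP/ridge regression, which is used as a cross-check in tests.
    """
    if not (0 <= pi < 1):
        raise ConfigurationError("pi must lie in [0, 1)")
    if n_iter <= n_burn:
        raise ConfigurationError("n_iter must exceed n_burn")
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    if not obs.any():
        raise ConfigurationError("no phenotyped individuals to train on")
    col_means = Z[obs].mean(axis=0)
    W_all = Z - col_means
    W = np.asfortranarray(W_all[obs])
    yc = y[obs] - y[obs].mean()
    n, m = W.shape
    vary = float(np.var(yc, ddof=1)) if n > 1 else 1.0
    if vary == 0:
        vary = 1.0

    p = col_means / 2.0
    sum2pq = float(np.sum(2.0 * p * (1.0 - p)))
    if sum2pq == 0:
        raise DegenerateDataError("all markers monomorphic; BayesB undefined")
    if scale is None:
        scale = h2 * vary * (df - 2.0) / (df * max(1.0 - pi, 1e-12) * sum2pq)
    nu_e = 4.0
    Se = (1.0 - h2) * vary

    update_marker_var = fixed_marker_variance is None
    sigma2_init = scale * df / (df - 2.0) if update_marker_var else float(fixed_marker_variance)
    update_resid_var = fixed_residual_variance is None
    sigma2e_init = (1.0 - h2) * vary if update_resid_var else float(fixed_residual_variance)

    alpha_mean, incl = _bayesb_gibbs(
        W,
        yc,
        float(pi),
        int(n_iter),
        int(n_burn),
        float(df),
        float(scale),
        nu_e,
        Se,
        update_marker_var,
        update_resid_var,
        float(sigma2_init),
        float(sigma2e_init),
        int(seed) & 0x7FFFFFFF,
    )
    if not (np.all(np.isfinite(alpha_mean)) and np.all(np.isfinite(incl))):
        raise NumericalError("BayesB chain produced non-finite samples")
    post = MarkerEffectPosterior(
        mean_effects=alpha_mean,
        inclusion_prob=incl,
        settings={
            "pi": pi,
            "n_iter": n_iter,
            "n_burn": n_burn,
            "df": df,
            "scale": scale,
            "seed": int(seed),
        },
    )
    ebv = W_all @ alpha_mean
    return ebv, post


def snp_blup_ebv(y: np.ndarray, Z: np.ndarray, h2: float, freqs=None) -> np.ndarray:
    """Ridge-regression (SNP-BLUP) breeding values.

    Marker effects solve ``(W'W + lam_s I) b = W'(y - mean)`` with
    ``W = Z - 2p`` and ``lam_s = 2 sum p(1-p) * (1-h2)/h2``; EBV = ``W b``.
    Equivalent to GBLUP with the VanRaden GRM on the same frequencies —
    used as the independent oracle for the GBLUP solver in tests.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if freqs is None:
        freqs = Z.mean(axis=0) / 2.0
    p = np.asarray(freqs, dtype=float)
    mask = (p > 0) & (p < 1)
    W = Z[:, mask] - 2.0 * p[mask]
    lam_s = 2.0 * np.sum(p[mask] * (1.0 - p[mask])) * (1.0 - h2) / h2
    m = W.shape[1]
    # profile out the mean: iterate mu and beta jointly via the normal
    # equations of [1 W]
    X = np.column_stack([np.ones(len(y)), W])
    pen = np.eye(m + 1) * lam_s
    pen[0, 0] = 0.0
    sol = np.linalg.solve(X.T @ X + pen, X.T @ y)
    return W @ sol[1:]
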