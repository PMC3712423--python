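"""Repeatability of repeated behavioural assays.

Repeatability (the intraclass correlation) is the fraction of phenotypic
variance, after adjusting for fixed effects, that is attributable to
consistent differences between individuals:

    R = sigma2_ind / (sigma2_ind + sigma2_res)

It is estimated from a Gaussian random-intercept model

    y_ij = x_ij' b + u_i + e_ij,   u_i ~ N(0, sigma2_ind),  e_ij ~ N(0, sigma2_res)

fitted by a Gibbs sampler with a flat prior on the fixed effects ``b`` and
weakly informative inverse-gamma(0.001, 0.001) priors on both variances.
R is computed per posterior draw, summarized by its kernel-density mode
(with the posterior mean alongside) and a 95% equal-tailed credible
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._summaries import equal_tailed_interval, kde_mode
from .mcmc import MCMCSettings

__all__ = [
    "MCMCSettings",
    "VarianceComponentsPosterior",
    "RepeatabilityEstimate",
    "fit_random_intercept",
    "repeatability",
    "sample_variance_posterior",
]

_PRIOR_SHAPE = 0.001
_PRIOR_SCALE = 0.001


@dataclass(frozen=True)
class VarianceComponentsPosterior:
    sigma2_ind: np.ndarray          # (k,) between-individual variance draws
    sigma2_res: np.ndarray          # (k,) residual variance draws
    fixed_effects: np.ndarray       # (k, q) fixed-effect draws
    fixed_names: tuple[str, ...]
    settings: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        if self.sigma2_ind.size == 0:
            raise ValueError("empty posterior")
        if np.any(self.sigma2_ind < 0) or np.any(self.sigma2_res <= 0):
            raise ValueError("variance draws must be positive")


@dataclass(frozen=True)
class RepeatabilityEstimate:
    point: float      # kernel-density mode of the per-draw R
    mean: float       # posterior mean of the per-draw R
    lower95: float
    upper95: float


def sample_variance_posterior(
    sum_sq: float,
    n: int,
    rng: np.random.Generator,
    shape: float = _PRIOR_SHAPE,
    scale: float = _PRIOR_SCALE,
) -> float:
    """One draw from the conditional inverse-gamma variance update:
    IG(shape + n/2, scale + sum_sq/2). This is the conjugate step used for
    both variance components."""
    a = shape + 0.5 * n
    b = scale + 0.5 * sum_sq
    return b / rng.gamma(a)


def fit_random_intercept(
    y,
    individual,
    covariates=None,
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
) -> VarianceComponentsPosterior:
    """Gibbs sampler for the Gaussian random-intercept model.

    Parameters
    ----------
    y
        Response vector (one entry per assay).
    individual
        Individual identity per assay (any hashable labels).
    covariates
        Optional fixed-effect design, an (n, q) array or a mapping of
        name -> column; an intercept column is always prepended.
    settings, seed
        Chain length and master seed.
    """
    y = np.asarray(y, dtype=float)
    individual = np.asarray(individual)
    if y.ndim != 1 or y.shape != individual.shape:
        raise ValueError("y and individual must be equal-length vectors")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing responses are not supported; drop them first")

    ids, ind_index = np.unique(individual, return_inverse=True)
    n_ind = ids.size
    counts = np.bincount(ind_index)
    if n_ind < 2 or np.sum(counts >= 2) < 2:
        raise ValueError("need at least 2 individuals with >= 2 measures each")

    names = ["intercept"]
    cols = [np.ones_like(y)]
    if covariates is not None:
        if hasattr(covariates, "items"):
            for name, col in covariates.items():
                names.append(str(name))
                cols.append(np.asarray(col, dtype=float))
        else:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != y.size:
                covariates = covariates.T
            for j in range(covariates.shape[1]):
                names.append(f"x{j + 1}")
                cols.append(covariates[:, j])
    X = np.column_stack(cols)
    n, q = X.shape
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("fixed-effect design matrix is singular")

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    chol_XtX_inv = np.linalg.cholesky(XtX_inv)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    b = XtX_inv @ (X.T @ y)
    u = np.zeros(n_ind)
    s2_ind, s2_res = 1.0, 1.0

    keep = settings.n_draws
    out_ind = np.empty(keep)
    out_res = np.empty(keep)
    out_b = np.empty((keep, q))
    k = 0
    for it in range(settings.n_iter):
        # fixed effects | rest  (flat prior)
        resid_u = y - u[ind_index]
        b_hat = XtX_inv @ (X.T @ resid_u)
        b = b_hat + np.sqrt(s2_res) * (chol_XtX_inv @ rng.standard_normal(q))

        # random intercepts | rest
        r = y - X @ b
        sums = np.bincount(ind_index, weights=r, minlength=n_ind)
        prec = counts / s2_res + 1.0 / s2_ind
        mean = (sums / s2_res) / prec
        u = mean + rng.standard_normal(n_ind) / np.sqrt(prec)

        # variances | rest
        s2_ind = sample_variance_posterior(float(u @ u), n_ind, rng)
        e = r - u[ind_index]
        s2_res = sample_variance_posterior(float(e @ e), n, rng)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            out_ind[k] = s2_ind
            out_res[k] = s2_res
            out_b[k] = b
            k += 1

    return VarianceComponentsPosterior(
        sigma2_ind=out_ind[:k],
        sigma2_res=out_res[:k],
        fixed_effects=out_b[:k],
        fixed_names=tuple(names),
        settings=settings,
    )


def repeatability(post: VarianceComponentsPosterior) -> RepeatabilityEstimate:
    """Per-draw R = sigma2_ind / (sigma2_ind + sigma2_res) summarized by
    its kernel-density mode, posterior mean and 95% credible interval."""
    r = post.sigma2_ind / (post.sigma2_ind + post.sigma2_res)
    lo, hi = equal_tailed_interval(r)
    return RepeatabilityEstimate(
        point=kde_mode(r), mean=float(r.mean()), lower95=lo, upper95=hi
    )
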