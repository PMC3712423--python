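"""Posterior draws of the trait variance-covariance matrix.

The analysis variables (behavioural scores, breeding variables and
reproductive success measures) are modelled as multivariate Gaussian with
unknown mean and covariance. Because every variable is observed on a
different subset of pairs, the sampler uses Gibbs data augmentation:
missing cells are drawn from their conditional Gaussian given the observed
cells, the mean is drawn given the completed data, and the covariance is
drawn from its inverse-Wishart full conditional. Missingness is treated
as ignorable (missing at random); augmentation keeps every draw a proper
positive-definite matrix, which pairwise-complete estimation would not.

Variables are standardized (observed mean 0, SD 1) before sampling, so
the draws live on the correlation-like scale the path analysis expects;
:func:`to_correlation` rescales each draw to exact unit diagonal.

Priors: inverse-Wishart with p + 1 degrees of freedom and identity scale
(marginal correlations near-uniform on the standardized scale) and a
near-flat Gaussian prior (variance 1e8) on the mean. The default chain
is 13 000 iterations, 3 000 burn-in, thinning 10 — exactly 1 000 retained
covariance matrices to carry forward into the path analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import MCMCSettings

__all__ = [
    "CovarianceDraws",
    "fit_mvn_missing",
    "pairwise_counts",
    "to_correlation",
    "save_draws",
    "load_draws",
]

_MEAN_PRIOR_VAR = 1e8


@dataclass(frozen=True)
class CovarianceDraws:
    """A sequence of posterior covariance (or correlation) matrices."""

    variables: tuple[str, ...]
    matrices: np.ndarray            # (k, p, p), each symmetric PD
    means: np.ndarray               # (k, p)
    pairwise_n: pd.DataFrame        # (p, p) joint observation counts
    settings: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int | None = None

    def __post_init__(self) -> None:
        k, p, p2 = self.matrices.shape
        if p != p2 or p != len(self.variables):
            raise ValueError("matrix dimensions do not match variables")
        if self.means.shape != (k, p):
            raise ValueError("means shape does not match draws")

    def __len__(self) -> int:
        return self.matrices.shape[0]


def pairwise_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Entry (i, j) = number of rows where both variables are observed."""
    obs = table.notna().to_numpy().astype(int)
    counts = obs.T @ obs
    return pd.DataFrame(counts, index=table.columns, columns=table.columns)


def fit_mvn_missing(
    table: pd.DataFrame,
    settings: MCMCSettings = MCMCSettings(),
    seed: int = 0,
    known_mean=None,
) -> CovarianceDraws:
    """Gibbs sampler for the covariance matrix under MVN with missing data.

    Parameters
    ----------
    table
        One column per analysis variable, NaN for missing. Rows with all
        variables missing are dropped; every variable needs >= 3 observed
        values and non-zero variance.
    settings, seed
        Chain settings and master seed.
    known_mean
        Optional fixed mean vector on the standardized scale. When given,
        the mean-update step is skipped, making the no-missing-data case
        exactly conjugate (inverse-Wishart posterior).
    """
    table = table.dropna(how="all")
    variables = tuple(str(c) for c in table.columns)
    p = len(variables)
    if p < 2:
        raise ValueError("need at least 2 variables")
    raw = table.to_numpy(dtype=float)
    obs = np.isfinite(raw)
    if np.any(obs.sum(axis=0) < 3):
        bad = [v for v, c in zip(variables, obs.sum(axis=0)) if c < 3]
        raise ValueError(f"variables observed on fewer than 3 rows: {bad}")

    mu_obs = np.array([raw[obs[:, j], j].mean() for j in range(p)])
    sd_obs = np.array([raw[obs[:, j], j].std(ddof=1) for j in range(p)])
    if np.any(sd_obs <= 0):
        bad = [v for v, s in zip(variables, sd_obs) if s <= 0]
        raise ValueError(f"zero-variance variables: {bad}")
    X = (raw - mu_obs) / sd_obs

    n_pair = pairwise_counts(table)
    if (n_pair.to_numpy() < 1).any():
        warnings.warn(
            "some variable pairs have no jointly observed rows; "
            "their covariance is informed only through imputation",
            stacklevel=2,
        )

    n = X.shape[0]
    X[~obs] = 0.0

    # group rows by missingness pattern for vectorized imputation
    patterns: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    if (~obs).any():
        keys = {}
        for i in range(n):
            key = obs[i].tobytes()
            keys.setdefault(key, []).append(i)
        for key, rows in keys.items():
            mask = np.frombuffer(key, dtype=bool)
            if mask.all():
                continue
            patterns.append(
                (np.where(~mask)[0], np.where(mask)[0], np.array(rows))
            )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    nu0 = p + 1
    S0 = np.eye(p)
    mu = np.zeros(p) if known_mean is None else np.asarray(known_mean, dtype=float)
    Sigma = np.eye(p)

    complete = not patterns
    if complete:
        G = X.T @ X
        xbar = X.mean(axis=0)

    keep = settings.n_draws
    out_S = np.empty((keep, p, p))
    out_mu = np.empty((keep, p))
    k = 0
    for it in range(settings.n_iter):
        if not complete:
            for miss, seen, rows in patterns:
                if seen.size == 0:
                    cond_mean = np.broadcast_to(mu[miss], (rows.size, miss.size))
                    cond_cov = Sigma[np.ix_(miss, miss)]
                else:
                    B = np.linalg.solve(
                        Sigma[np.ix_(seen, seen)], Sigma[np.ix_(seen, miss)]
                    ).T
                    cond_mean = mu[miss] + (X[np.ix_(rows, seen)] - mu[seen]) @ B.T
                    cond_cov = Sigma[np.ix_(miss, miss)] - B @ Sigma[np.ix_(seen, miss)]
                L = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(miss.size))
                X[np.ix_(rows, miss)] = (
                    cond_mean + rng.standard_normal((rows.size, miss.size)) @ L.T
                )
            G = X.T @ X
            xbar = X.mean(axis=0)

        if known_mean is None:
            Sigma_inv = np.linalg.inv(Sigma)
            prec = n * Sigma_inv + np.eye(p) / _MEAN_PRIOR_VAR
            cov_mu = np.linalg.inv(prec)
            mean_mu = cov_mu @ (n * Sigma_inv @ xbar)
            mu = rng.multivariate_normal(mean_mu, cov_mu, method="cholesky")

        S = G - n * (np.outer(mu, xbar) + np.outer(xbar, mu)) + n * np.outer(mu, mu)
        S = (S + S.T) / 2.0
        Sigma = stats.invwishart.rvs(df=nu0 + n, scale=S0 + S, random_state=rng)
        Sigma = (Sigma + Sigma.T) / 2.0

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            out_S[k] = Sigma
            out_mu[k] = mu
            k += 1

    return CovarianceDraws(
        variables=variables,
        matrices=out_S[:k],
        means=out_mu[:k],
        pairwise_n=n_pair,
        settings=settings,
        seed=seed,
    )


def to_correlation(draws: CovarianceDraws) -> CovarianceDraws:
    """Rescale every draw to unit diagonal (positive-definiteness is
    preserved by the congruence transform)."""
    d = np.diagonal(draws.matrices, axis1=1, axis2=2)
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal entry in a covariance draw")
    scale = 1.0 / np.sqrt(d)
    mats = draws.matrices * scale[:, :, None] * scale[:, None, :]
    return replace(draws, matrices=mats, means=draws.means * scale)


def save_draws(draws: CovarianceDraws, directory) -> None:
    """Archive draws as ``draws.npz`` plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "draws.npz",
        matrices=draws.matrices,
        means=draws.means,
        pairwise_n=draws.pairwise_n.to_numpy(),
    )
    manifest = {
        "variables": list(draws.variables),
        "n_draws": len(draws),
        "seed": draws.seed,
        "settings": {
            "n_iter": draws.settings.n_iter,
            "burn_in": draws.settings.burn_in,
            "thin": draws.settings.thin,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_draws(directory) -> CovarianceDraws:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    arrays = np.load(directory / "draws.npz")
    variables = tuple(manifest["variables"])
    return CovarianceDraws(
        variables=variables,
        matrices=arrays["matrices"],
        means=arrays["means"],
        pairwise_n=pd.DataFrame(
            arrays["pairwise_n"], index=list(variables), columns=list(variables)
        ),
        settings=MCMCSettings(**manifest["settings"]),
        seed=manifest["seed"],
    )
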