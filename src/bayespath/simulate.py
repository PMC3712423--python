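"""Synthetic pair-level data with a known structural model.

The generator draws one row per breeding pair from a standardized
recursive structural model: exogenous traits are jointly Gaussian with the
configured correlations, and each endogenous trait is the coefficient-
weighted sum of its parents plus a Gaussian residual whose variance is
chosen so every latent trait has unit variance. Coefficients are therefore
directly comparable to standardized path coefficients estimated from the
generated data.

On top of the latent traits the generator can layer the measurement
structure of a provisioning field study: repeated behavioural assays with a
configured intraclass correlation (repeatability), a nest-stage effect on
the approach-latency assay of aggression, and observation-scale transforms
(latencies in seconds, nest-visit counts per 90-minute window on two
observation days, integer lay dates and brood sizes). Latent columns are
always retained alongside the observation-scale columns, so parameter-
recovery analyses can bypass rounding attenuation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InvalidCoefficientError",
    "GeneratorConfig",
    "TrueParameters",
    "generate_population",
    "apply_missingness",
    "write_trait_table",
    "read_trait_table",
]


class InvalidCoefficientError(ValueError):
    """The configured structural model implies a non-positive residual
    variance or a non-positive-definite exogenous correlation block."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Population-level ground truth for one synthetic dataset.

    Parameters
    ----------
    n_pairs
        Number of breeding pairs (rows).
    coefficients
        Directed-edge map ``(source, target) -> beta`` of standardized path
        coefficients; the directed part must be acyclic.
    exog_correlations
        Map ``(a, b) -> rho`` of correlations between exogenous traits.
    repeat_icc
        Map ``variable -> R`` giving the repeatability (intraclass
        correlation) of its two repeated measures.
    stage_effects
        Map ``nest-stage label -> offset`` added to log approach latency;
        stages are assigned to pairs uniformly at random.
    missing_rates
        Map ``column -> rate`` applied after generation (MCAR).
    observation_scale
        If true, emit field-scale columns (latency seconds, visit counts,
        integer dates/brood sizes) in addition to the latent columns.
    seed
        Seed for all randomness in the generator.
    """

    n_pairs: int
    coefficients: dict[tuple[str, str], float]
    exog_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    repeat_icc: dict[str, float] = field(default_factory=dict)
    stage_effects: dict[str, float] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    observation_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        for (a, b) in self.coefficients:
            if a == b:
                raise InvalidCoefficientError(f"self-edge on {a!r}")
        g = nx.DiGraph(list(self.coefficients))
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidCoefficientError("structural coefficients contain a cycle")
        for v, r in self.repeat_icc.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"repeat_icc[{v!r}] = {r} outside [0, 1]")
        for v, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing_rates[{v!r}] = {r} outside [0, 1]")
        for (a, b), r in self.exog_correlations.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"exog correlation {a}~{b} = {r} outside (-1, 1)")

    @property
    def variables(self) -> tuple[str, ...]:
        """All structural variables, in deterministic topological order."""
        seen: list[str] = []
        for (a, b) in self.coefficients:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        for (a, b) in self.exog_correlations:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        g = nx.DiGraph(list(self.coefficients))
        g.add_nodes_from(seen)
        index = {v: i for i, v in enumerate(seen)}
        return tuple(nx.lexicographical_topological_sort(g, key=index.get))


@dataclass(frozen=True)
class TrueParameters:
    """Realized ground truth: coefficients, residual variances, the implied
    population correlation matrix and the repeat-measure variance split."""

    coefficients: dict[tuple[str, str], float]
    exog_correlations: dict[tuple[str, str], float]
    residual_variances: dict[str, float]
    implied_correlation: pd.DataFrame
    repeat_icc: dict[str, float]

    def to_json(self, path) -> None:
        payload = {
            "coefficients": {f"{a}->{b}": v for (a, b), v in self.coefficients.items()},
            "exog_correlations": {
                f"{a}<->{b}": v for (a, b), v in self.exog_correlations.items()
            },
            "residual_variances": self.residual_variances,
            "implied_correlation": {
                "variables": list(self.implied_correlation.columns),
                "matrix": self.implied_correlation.to_numpy().tolist(),
            },
            "repeat_icc": self.repeat_icc,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _implied_correlation(config: GeneratorConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Population correlation matrix and residual variances by the
    forward recursion: for endogenous y, cov(y, u) = sum_p beta_p cov(p, u)
    and var(y) = 1 with psi_y = 1 - beta' R_P beta."""
    order = config.variables
    idx = {v: i for i, v in enumerate(order)}
    p = len(order)
    parents = {v: [a for (a, b) in config.coefficients if b == v] for v in order}

    S = np.zeros((p, p))
    resid: dict[str, float] = {}
    exog = [v for v in order if not parents[v]]
    for v in exog:
        S[idx[v], idx[v]] = 1.0
    for (a, b), r in config.exog_correlations.items():
        if parents.get(a) or parents.get(b):
            raise InvalidCoefficientError(
                f"exogenous correlation {a}~{b} touches an endogenous variable"
            )
        S[idx[a], idx[b]] = r
        S[idx[b], idx[a]] = r
    exog_idx = [idx[v] for v in exog]
    if exog_idx:
        eig = np.linalg.eigvalsh(S[np.ix_(exog_idx, exog_idx)])
        if eig.min() <= 0:
            raise InvalidCoefficientError(
                "exogenous correlation block is not positive definite"
            )

    for v in order:
        if not parents[v]:
            continue
        i = idx[v]
        P = [idx[a] for a in parents[v]]
        beta = np.array([config.coefficients[(a, v)] for a in parents[v]])
        explained = float(beta @ S[np.ix_(P, P)] @ beta)
        psi = 1.0 - explained
        if psi <= 0:
            raise InvalidCoefficientError(
                f"parents of {v!r} explain {explained:.3f} >= 100% of its variance"
            )
        resid[v] = psi
        cov = S[:, P] @ beta
        S[i, :] = cov
        S[:, i] = cov
        S[i, i] = 1.0

    return pd.DataFrame(S, index=list(order), columns=list(order)), resid


# observation-scale realism constants: typical blue tit field values
_LATENCY_SLOPE = 0.5          # aggression latent -> log latency (inverted sign)
_LATENCY_BASE_S = 60.0
_FEED_MEAN, _FEED_SD = 15.0, 4.0       # feeds per hour
_EXPLORE_MEAN, _EXPLORE_SD = 15.0, 6.0  # hops+flights in 5 min
_LAYDATE_MEAN, _LAYDATE_SD = 20.0, 8.0  # days since March 1
_BROOD_MEAN, _BROOD_SD = 9.0, 2.5
_FLEDGE_MEAN, _FLEDGE_SD = 8.0, 2.5
_MASS_MEAN, _MASS_SD = 11.2, 0.9       # grams

_FEED_VARS = ("own_feed_rate", "partner_feed_rate", "feed_rate_m", "feed_rate_f")


def generate_population(config: GeneratorConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """Draw a pair-level trait table from the configured structural model.

    Returns the table (one row per pair; latent columns always present)
    and the realized :class:`TrueParameters`. Missingness is *not* applied
    here — use :func:`apply_missingness` so complete and degraded versions
    of the same population can be compared.
    """
    implied, resid = _implied_correlation(config)
    order = config.variables
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_pairs

    parents = {v: [a for (a, b) in config.coefficients if b == v] for v in order}
    latents: dict[str, np.ndarray] = {}

    exog = [v for v in order if not parents[v]]
    if exog:
        R0 = implied.loc[exog, exog].to_numpy()
        L = np.linalg.cholesky(R0)
        Z = rng.standard_normal((n, len(exog))) @ L.T
        for j, v in enumerate(exog):
            latents[v] = Z[:, j]
    for v in order:
        if not parents[v]:
            continue
        mean = np.zeros(n)
        for a in parents[v]:
            mean += config.coefficients[(a, v)] * latents[a]
        latents[v] = mean + np.sqrt(resid[v]) * rng.standard_normal(n)

    table = pd.DataFrame({"pair_id": np.arange(1, n + 1)})
    for v in order:
        table[v] = latents[v]

    # repeated assays: measure = latent + noise, noise variance (1-R)/R
    for v, icc in config.repeat_icc.items():
        if v not in latents:
            raise KeyError(f"repeat_icc names unknown variable {v!r}")
        for rep in (1, 2):
            if icc == 0.0:
                meas = rng.standard_normal(n)
            elif icc == 1.0:
                meas = latents[v].copy()
            else:
                meas = latents[v] + np.sqrt((1.0 - icc) / icc) * rng.standard_normal(n)
            table[f"{v}_rep{rep}"] = meas

    if config.observation_scale:
        _add_observation_columns(table, latents, config, rng)

    truth = TrueParameters(
        coefficients=dict(config.coefficients),
        exog_correlations=dict(config.exog_correlations),
        residual_variances=resid,
        implied_correlation=implied,
        repeat_icc=dict(config.repeat_icc),
    )
    return table, truth


def _add_observation_columns(
    table: pd.DataFrame,
    latents: dict[str, np.ndarray],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    n = config.n_pairs
    if "aggression" in latents:
        stages = list(config.stage_effects) or ["nestling"]
        offsets = {s: config.stage_effects.get(s, 0.0) for s in stages}
        assigned = rng.choice(stages, size=n)
        table["nest_stage"] = assigned
        off = np.array([offsets[s] for s in assigned])
        # monotone decreasing map: more aggressive -> shorter approach latency
        table["latency_s"] = np.exp(off - _LATENCY_SLOPE * latents["aggression"]) * _LATENCY_BASE_S

    for v in latents:
        if v in _FEED_VARS:
            for rep, day in ((1, 11), (2, 14)):
                col = f"{v}_rep{rep}"
                z = table[col].to_numpy() if col in table else latents[v]
                hourly = np.clip(_FEED_MEAN + _FEED_SD * z, 0.0, None)
                table[f"{v}_visits_day{day}"] = np.rint(hourly * 1.5).astype(int)
        elif v == "exploration":
            for rep in (1, 2):
                col = f"{v}_rep{rep}"
                z = table[col].to_numpy() if col in table else latents[v]
                table[f"{v}_count{rep}"] = np.rint(
                    np.clip(_EXPLORE_MEAN + _EXPLORE_SD * z, 0.0, None)
                ).astype(int)
        elif v == "lay_date":
            table["lay_date_obs"] = np.rint(
                _LAYDATE_MEAN + _LAYDATE_SD * latents[v]
            ).astype(int)
        elif v == "brood_size":
            table["brood_size_obs"] = np.clip(
                np.rint(_BROOD_MEAN + _BROOD_SD * latents[v]), 0, None
            ).astype(int)
        elif v == "fledgling_no":
            fledged = np.clip(
                np.rint(_FLEDGE_MEAN + _FLEDGE_SD * latents[v]), 0, None
            ).astype(int)
            if "brood_size_obs" in table:
                fledged = np.minimum(fledged, table["brood_size_obs"].to_numpy())
            table["fledgling_no_obs"] = fledged
        elif v == "fledgling_mass":
            table["fledgling_mass_g"] = np.clip(
                _MASS_MEAN + _MASS_SD * latents[v], 1.0, None
            )


def apply_missingness(table: pd.DataFrame, rates: dict[str, float], seed: int) -> pd.DataFrame:
    """Independently blank each cell of each named column with its rate
    (missing completely at random); other columns are untouched."""
    out = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for col, rate in rates.items():
        if col not in out.columns:
            raise KeyError(f"unknown variable {col!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col!r} outside [0, 1]")
        mask = rng.random(len(out)) < rate
        if out[col].dtype.kind in "iub":
            out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan
    return out


def write_trait_table(table: pd.DataFrame, path) -> None:
    """UTF-8 CSV with header; missing cells written as ``NA``."""
    table.to_csv(path, index=False, na_rep="NA")


def read_trait_table(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True)
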