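import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bayespath as bp

SHORT = bp.MCMCSettings(n_iter=2600, burn_in=600, thin=2)


def _bivariate(n, rho, seed, missing=None):
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    data = rng.multivariate_normal([0, 0], cov, size=n)
    frame = pd.DataFrame(data, columns=["x", "y"])
    if missing:
        col, rate = missing
        frame.loc[rng.random(n) < rate, col] = np.nan
    return frame


class TestPairwiseCounts:
    def test_counts_joint_observations(self):
        t = pd.DataFrame({"A": [1.0, 2.0, np.nan], "B": [1.0, 1.0, 1.0]})
        n = bp.pairwise_counts(t)
        assert n.loc["A", "B"] == 2
        assert n.loc["B", "B"] == 3
        assert n.loc["A", "A"] == 2

    def test_complete_table_is_constant(self):
        t = pd.DataFrame(np.ones((48, 3)), columns=list("abc"))
        assert (bp.pairwise_counts(t).to_numpy() == 48).all()

    def test_disjoint_patterns_give_zero(self):
        t = pd.DataFrame({"A": [1.0, np.nan], "B": [np.nan, 1.0]})
        assert bp.pairwise_counts(t).loc["A", "B"] == 0


class TestToCorrelation:
    def test_identity_is_fixed_point(self):
        d = _draws(np.eye(3)[None, :, :])
        np.testing.assert_allclose(bp.to_correlation(d).matrices[0], np.eye(3))

    def test_covariance_rescales_to_correlation(self):
        S = np.array([[4.0, 3.0], [3.0, 9.0]])
        d = _draws(S[None, :2, :2], p=2)
        out = bp.to_correlation(d).matrices[0]
        assert out[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(out), 1.0)

    def test_random_pd_matrix_stays_pd_with_unit_diagonal(self, rng):
        A = rng.standard_normal((3, 6))
        d = _draws((A @ A.T)[None, :, :])
        out = bp.to_correlation(d).matrices[0]
        np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(out).min() > 0

    def test_zero_diagonal_errors(self):
        S = np.diag([1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="diagonal"):
            bp.to_correlation(_draws(S[None, :, :]))


def _draws(mats, p=None):
    p = p or mats.shape[1]
    names = tuple(f"v{i}" for i in range(p))
    return bp.CovarianceDraws(
        variables=names,
        matrices=mats,
        means=np.zeros((mats.shape[0], p)),
        pairwise_n=pd.DataFrame(np.ones((p, p)), index=names, columns=names),
    )


def test_posterior_mean_tracks_sample_correlation_without_missingness():
    frame = _bivariate(500, 0.5, seed=1)
    draws = bp.fit_mvn_missing(frame, settings=SHORT, seed=2)
    corr = bp.to_correlation(draws)
    post_mean = corr.matrices[:, 0, 1].mean()
    assert post_mean == pytest.approx(frame.corr().iloc[0, 1], abs=0.05)
    assert (draws.pairwise_n.to_numpy() == 500).all()


def test_known_mean_no_missing_matches_inverse_wishart_closed_form():
    """With a fixed mean and complete data the sampler's draws are iid
    from IW(p + 1 + n, I + X'X) on the standardized scale."""
    frame = _bivariate(200, 0.4, seed=3)
    settings = bp.MCMCSettings(n_iter=2000, burn_in=0, thin=1)
    draws = bp.fit_mvn_missing(frame, settings=settings, seed=4, known_mean=[0.0, 0.0])

    X = (frame - frame.mean()) / frame.std(ddof=1)
    scale = np.eye(2) + X.to_numpy().T @ X.to_numpy()
    df = 2 + 1 + 200
    # diagonal entries: exact scaled-inverse-chi-square marginals
    for j in range(2):
        dist = stats.invgamma(a=(df - 2 + 1) / 2, scale=scale[j, j] / 2)
        ks = stats.kstest(draws.matrices[:, j, j], dist.cdf).statistic
        assert ks < 0.05
    # off-diagonal entry: two-sample KS against direct inverse-Wishart draws
    ref = stats.invwishart.rvs(df=df, scale=scale, size=4000,
                               random_state=np.random.default_rng(5))
    ks = stats.ks_2samp(draws.matrices[:, 0, 1], ref[:, 0, 1]).statistic
    assert ks < 0.05


def test_mcar_missingness_recovers_generating_correlation():
    frame = _bivariate(1000, 0.5, seed=6, missing=("y", 0.2))
    draws = bp.fit_mvn_missing(frame, settings=SHORT, seed=7)
    post_mean = bp.to_correlation(draws).matrices[:, 0, 1].mean()
    assert post_mean == pytest.approx(0.5, abs=0.07)


def test_imputation_consistency_under_heavier_mcar():
    """30% MCAR shifts posterior-mean correlations by < 0.08 on average
    relative to the complete-data posterior."""
    tiny = bp.MCMCSettings(n_iter=1600, burn_in=600, thin=1)
    diffs = []
    for seed in range(10):
        frame = _bivariate(1000, 0.5, seed=100 + seed)
        full = bp.fit_mvn_missing(frame, settings=tiny, seed=seed)
        rng = np.random.default_rng(200 + seed)
        degraded = frame.copy()
        degraded.loc[rng.random(1000) < 0.3, "y"] = np.nan
        part = bp.fit_mvn_missing(degraded, settings=tiny, seed=seed)
        a = bp.to_correlation(full).matrices[:, 0, 1].mean()
        b = bp.to_correlation(part).matrices[:, 0, 1].mean()
        diffs.append(abs(a - b))
    assert np.mean(diffs) < 0.08


def test_every_draw_is_symmetric_positive_definite():
    frame = _bivariate(300, 0.3, seed=8, missing=("x", 0.25))
    frame["z"] = frame["x"].fillna(0) * 0.5 + np.random.default_rng(9).normal(size=300)
    draws = bp.fit_mvn_missing(frame, settings=SHORT, seed=10)
    asym = np.abs(draws.matrices - np.transpose(draws.matrices, (0, 2, 1))).max()
    assert asym < 1e-12
    eigs = np.linalg.eigvalsh(draws.matrices)
    assert eigs.min() > 0
    assert len(draws) == SHORT.n_draws


def test_input_validation_and_degenerate_pairs():
    with pytest.raises(ValueError, match="at least 2"):
        bp.fit_mvn_missing(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
    const = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="zero-variance"):
        bp.fit_mvn_missing(const, settings=SHORT)
    sparse = pd.DataFrame({"x": [1.0, 2.0, 3.0, np.nan, np.nan, np.nan],
                           "y": [np.nan, np.nan, np.nan, 1.0, 2.0, 3.0]})
    with pytest.warns(UserWarning, match="jointly observed"):
        bp.fit_mvn_missing(sparse, settings=bp.MCMCSettings(300, 100, 1), seed=1)


def test_archive_round_trip(tmp_path):
    frame = _bivariate(100, 0.2, seed=11)
    draws = bp.fit_mvn_missing(frame, settings=bp.MCMCSettings(400, 100, 1), seed=12)
    bp.save_draws(draws, tmp_path / "arch")
    back = bp.load_draws(tmp_path / "arch")
    np.testing.assert_allclose(back.matrices, draws.matrices)
    assert back.variables == draws.variables
    assert back.settings == draws.settings
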