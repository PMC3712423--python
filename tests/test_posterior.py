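import numpy as np
import pandas as pd
import pytest

import bayespath as bp
from bayespath.posterior import PropagationError, _repair_correlation
from conftest import make_fit, traced_implied_matrix


def _make_draws(mats, variables):
    mats = np.asarray(mats, dtype=float)
    p = len(variables)
    return bp.CovarianceDraws(
        variables=tuple(variables),
        matrices=mats,
        means=np.zeros((mats.shape[0], p)),
        pairwise_n=pd.DataFrame(
            np.full((p, p), 48), index=list(variables), columns=list(variables)
        ),
    )


@pytest.fixture(scope="module")
def chain_diagram():
    return bp.parse_diagram("1: X -> Y\n2: Y -> Z")


@pytest.fixture(scope="module")
def chain_matrix():
    fit = make_fit(bp.parse_diagram("1: X -> Y\n2: Y -> Z"), {"1": 0.6, "2": 0.5})
    return bp.implied_matrix(fit.diagram, fit)


def test_identical_draws_collapse_to_the_single_matrix_fit(chain_diagram, chain_matrix):
    draws = _make_draws(np.repeat(chain_matrix[None], 200, axis=0), ("X", "Y", "Z"))
    coef = bp.propagate(draws, chain_diagram, {"C": ("1", "2")})
    single = bp.fit_paths(chain_matrix, chain_diagram)
    for lbl in ("1", "2"):
        assert np.ptp(coef[lbl]) == 0.0
        assert coef[lbl][0] == pytest.approx(single.coefficients[lbl])
    assert coef["C"][0] == pytest.approx(0.3)
    s = bp.summarize(coef["1"], n_pair=48, label="1")
    assert s.upper95 - s.lower95 == 0.0
    assert s.p == pytest.approx(1 / 200)


def test_small_jitter_produces_small_coefficient_spread(chain_diagram, chain_matrix, rng):
    base = np.repeat(chain_matrix[None], 500, axis=0)
    jitter = rng.normal(0.0, 1e-3, size=base.shape)
    jitter = (jitter + np.transpose(jitter, (0, 2, 1))) / 2
    idx = np.arange(3)
    jitter[:, idx, idx] = 0.0
    draws = _make_draws(base + jitter, ("X", "Y", "Z"))
    coef = bp.propagate(draws, chain_diagram)
    for lbl in ("1", "2"):
        assert coef[lbl].std() < 1e-2


def test_widening_draw_dispersion_never_narrows_intervals(chain_diagram, chain_matrix, rng):
    widths = []
    for scale in (1e-3, 1e-2, 1e-1):
        jitter = rng.normal(0.0, scale, size=(400, 3, 3))
        jitter = (jitter + np.transpose(jitter, (0, 2, 1))) / 2
        idx = np.arange(3)
        jitter[:, idx, idx] = 0.0
        draws = _make_draws(np.repeat(chain_matrix[None], 400, axis=0) + jitter,
                            ("X", "Y", "Z"))
        coef = bp.propagate(draws, chain_diagram)
        s = bp.summarize(coef["1"], label="1")
        widths.append(s.upper95 - s.lower95)
    assert widths[0] <= widths[1] <= widths[2]


def test_per_draw_implied_matrix_satisfies_sum_of_paths(rng):
    """For each propagated draw the fitted model's implied correlations
    equal the exhaustive tracing-rule sum over connecting paths."""
    from conftest import random_recursive_model

    diagram, coefs = random_recursive_model(rng, n_vars=5)
    fit0 = make_fit(diagram, coefs)
    base = bp.implied_matrix(diagram, fit0)
    for _ in range(20):
        jitter = rng.normal(0, 5e-3, size=base.shape)
        jitter = (jitter + jitter.T) / 2
        np.fill_diagonal(jitter, 0.0)
        corr = _repair_correlation(base + jitter)
        fit = bp.fit_paths(corr, diagram)
        implied = bp.implied_matrix(diagram, fit)
        traced = traced_implied_matrix(diagram, fit)
        assert np.max(np.abs(implied - traced)) < 1e-10


def test_compound_summary_uses_per_draw_products():
    # two perfectly correlated coefficients: E[b1*b2] = 1, E[b1]*E[b2] = 0
    x = np.concatenate([np.full(500, 1.0), np.full(500, -1.0)])
    per_draw_products = x * x
    assert abs(per_draw_products.mean() - x.mean() * x.mean()) > 1e-3


class TestSummarize:
    def test_constant_vector(self):
        s = bp.summarize(np.full(1000, 0.43), n_pair=48, label="13")
        assert s.point == pytest.approx(0.43)
        assert (s.lower95, s.upper95) == (pytest.approx(0.43), pytest.approx(0.43))
        assert s.p == pytest.approx(1 / 1000)
        assert s.support == "strong"

    def test_balanced_signs_give_p_one(self):
        v = np.concatenate([np.full(500, -1.0), np.full(500, 1.0)])
        s = bp.summarize(v)
        assert s.p == 1.0
        assert s.p_positive == pytest.approx(0.5)
        assert s.support == "none"

    def test_gaussian_quantiles(self, rng):
        v = rng.normal(0.3, 0.1, size=100_000)
        s = bp.summarize(v)
        assert s.lower95 == pytest.approx(0.104, abs=0.01)
        assert s.upper95 == pytest.approx(0.496, abs=0.01)
        assert s.mean == pytest.approx(0.3, abs=0.005)

    def test_too_few_draws_error(self):
        with pytest.raises(ValueError, match="100 draws"):
            bp.summarize(np.ones(50))
        with pytest.raises(ValueError, match="empty"):
            bp.summarize(np.array([]))


@pytest.mark.parametrize(
    "lower, upper, p, expected",
    [
        (0.12, 0.68, 0.001, "strong"),
        (-0.68, -0.12, 0.001, "strong"),
        (-0.62, 0.02, 0.04, "some"),
        (-0.02, 0.62, 0.04, "some"),
        (-0.3, 0.3, 0.5, "none"),
        (0.0, 0.4, 0.06, "none"),
    ],
)
def test_support_classification_rule(lower, upper, p, expected):
    assert bp.classify_support(lower, upper, p) == expected


def test_indefinite_draws_are_rejected_and_capped(chain_diagram, chain_matrix):
    bad = np.eye(3)
    bad[0, 1] = bad[1, 0] = 1.2   # decidedly indefinite correlation
    good = np.repeat(chain_matrix[None], 98, axis=0)
    ok = _make_draws(np.concatenate([good, np.repeat(bad[None], 2, axis=0)]),
                     ("X", "Y", "Z"))
    coef = bp.propagate(ok, chain_diagram)
    assert len(coef["1"]) == 98

    many_bad = _make_draws(
        np.concatenate([good, np.repeat(bad[None], 10, axis=0)]), ("X", "Y", "Z")
    )
    with pytest.raises(PropagationError, match="rejected"):
        bp.propagate(many_bad, chain_diagram)


def test_report_table_and_dot_rendering(male_diagram, chain_diagram, chain_matrix):
    draws = _make_draws(np.repeat(chain_matrix[None], 150, axis=0), ("X", "Y", "Z"))
    coef = bp.propagate(draws, chain_diagram, {"C": ("1", "2")})
    summaries = bp.summarize_all(coef, chain_diagram, {"C": ("1", "2")},
                                 draws.pairwise_n)
    frame = bp.report(summaries)
    assert len(frame) == 3      # two direct paths + one compound
    assert list(frame["path"]) == ["1", "2", "C"]
    assert set(frame.columns) >= {"path", "link", "n", "path_coef",
                                  "lower95", "upper95", "p", "support"}

    dot = bp.report_dot(summaries, chain_diagram)
    assert "style=solid" in dot

    # a 'none' path must be omitted, a 'some' path dashed
    mixed = [
        bp.EdgeSummary("1", "X -> Y", 0.5, 0.5, 0.1, 0.9, 0.001, 1.0, "strong", 48),
        bp.EdgeSummary("2", "Y -> Z", 0.3, 0.3, -0.02, 0.6, 0.04, 0.98, "some", 48),
    ]
    dot = bp.report_dot(mixed, chain_diagram)
    assert "style=dashed" in dot
    none_case = [
        bp.EdgeSummary("1", "X -> Y", 0.0, 0.0, -0.3, 0.3, 0.5, 0.5, "none", 48),
        bp.EdgeSummary("2", "Y -> Z", 0.3, 0.3, 0.1, 0.6, 0.001, 1.0, "strong", 48),
    ]
    dot = bp.report_dot(none_case, chain_diagram)
    assert '"X" -> "Y"' not in dot


def test_full_report_row_count_matches_edges_plus_compounds(male_diagram):
    cfg = bp.presets.male_generator_config(n_pairs=800, seed=21)
    table, _ = bp.generate_population(cfg)
    draws = bp.fit_mvn_missing(table[list(male_diagram.variables)],
                               settings=bp.MCMCSettings(1600, 600, 2), seed=22)
    coef = bp.propagate(draws, male_diagram, bp.presets.MALE_COMPOUND_PATHS)
    summaries = bp.summarize_all(coef, male_diagram,
                                 bp.presets.MALE_COMPOUND_PATHS, draws.pairwise_n)
    frame = bp.report(summaries)
    assert len(frame) == 19 + len(bp.presets.MALE_COMPOUND_PATHS)
    # without compounds only the 19 simple paths remain
    plain = bp.summarize_all(coef, male_diagram, None, draws.pairwise_n)
    assert len(bp.report(plain)) == 19
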