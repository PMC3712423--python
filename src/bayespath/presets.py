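"""Study presets: the blue tit provisioning path models.

The hypothesized male model links aggressiveness and exploratory behaviour
(the aggression–exploration syndrome) to reproductive success through
parental provisioning and the female's breeding decisions: 19 directed
paths over 8 variables (aggression, exploration, lay date, brood size, own
and partner feeding rate, fledgling number and mean fledgling mass). The
female model is identical except that aggression was not assayed, leaving
14 paths over 7 variables. "Own" feeding rate is the focal sex's rate.

Point estimates published for a wild blue tit population are bundled here
so synthetic populations with realistic effect sizes can be generated and
the full inference chain exercised without field data. Repeatabilities of
the two behavioural assays from the same study are included for the
variance-components module.
"""

from __future__ import annotations

from .diagrams import PathDiagram, parse_diagram
from .simulate import GeneratorConfig

__all__ = [
    "MALE_PATHS",
    "FEMALE_PATHS",
    "MALE_COMPOUND_PATHS",
    "FEMALE_COMPOUND_PATHS",
    "EXPLORATION_REPEATABILITY_2011",
    "EXPLORATION_REPEATABILITY_COMBINED",
    "FEEDING_RATE_REPEATABILITY",
    "male_diagram",
    "female_diagram",
    "male_coefficients",
    "female_coefficients",
    "generator_config",
    "male_generator_config",
    "female_generator_config",
]

# (path label, source, target, point estimate, pairwise n)
MALE_PATHS: tuple[tuple[str, str, str, float, int], ...] = (
    ("1", "aggression", "exploration", 0.27, 41),
    ("2", "aggression", "own_feed_rate", -0.49, 33),
    ("3", "aggression", "fledgling_no", -0.06, 45),
    ("4", "aggression", "fledgling_mass", -0.27, 44),
    ("5", "aggression", "lay_date", 0.23, 43),
    ("6", "exploration", "own_feed_rate", 0.22, 44),
    ("7", "exploration", "fledgling_no", 0.10, 60),
    ("8", "exploration", "fledgling_mass", 0.03, 59),
    ("9", "exploration", "lay_date", -0.20, 58),
    ("10", "own_feed_rate", "partner_feed_rate", -0.59, 48),
    ("11", "own_feed_rate", "fledgling_no", 0.19, 48),
    ("12", "own_feed_rate", "fledgling_mass", -0.14, 48),
    ("13", "partner_feed_rate", "fledgling_no", 0.43, 48),
    ("14", "partner_feed_rate", "fledgling_mass", 0.16, 48),
    ("15", "lay_date", "brood_size", -0.52, 67),
    ("16", "brood_size", "own_feed_rate", 0.41, 48),
    ("17", "brood_size", "partner_feed_rate", 0.56, 48),
    ("18", "brood_size", "fledgling_no", 0.52, 69),
    ("19", "brood_size", "fledgling_mass", -0.53, 66),
)

FEMALE_PATHS: tuple[tuple[str, str, str, float, int], ...] = (
    ("6", "exploration", "own_feed_rate", 0.55, 37),
    ("7", "exploration", "fledgling_no", -0.12, 56),
    ("8", "exploration", "fledgling_mass", -0.07, 55),
    ("9", "exploration", "lay_date", -0.38, 54),
    ("10", "own_feed_rate", "partner_feed_rate", -0.56, 48),
    ("11", "own_feed_rate", "fledgling_no", 0.52, 48),
    ("12", "own_feed_rate", "fledgling_mass", 0.23, 48),
    ("13", "partner_feed_rate", "fledgling_no", 0.17, 48),
    ("14", "partner_feed_rate", "fledgling_mass", 0.03, 48),
    ("15", "lay_date", "brood_size", -0.50, 71),
    ("16", "brood_size", "own_feed_rate", 0.66, 48),
    ("17", "brood_size", "partner_feed_rate", 0.29, 48),
    ("18", "brood_size", "fledgling_no", 0.53, 73),
    ("19", "brood_size", "fledgling_mass", -0.47, 69),
)

# compound (indirect) paths: label -> ordered chain of path labels
MALE_COMPOUND_PATHS: dict[str, tuple[str, ...]] = {
    "A": ("10", "13"),
    "B": ("17", "13"),
    "C": ("2", "10", "13"),
    "D": ("1", "2"),
}
FEMALE_COMPOUND_PATHS: dict[str, tuple[str, ...]] = {
    "B": ("16", "11"),
    "E": ("6", "11"),
    "F": ("9", "15"),
    "G": ("9", "15", "18"),
    "H": ("9", "15", "19"),
}

# repeatabilities (intraclass correlations) of the behavioural assays
EXPLORATION_REPEATABILITY_2011 = 0.60
EXPLORATION_REPEATABILITY_COMBINED = 0.66
FEEDING_RATE_REPEATABILITY = 0.78

# approximate per-column MCAR rates reproducing the study's pairwise
# sample sizes (33-73 out of ~73 monitored nests)
FIELD_MISSING_RATES: dict[str, float] = {
    "aggression": 0.40,
    "exploration": 0.20,
    "own_feed_rate": 0.34,
    "partner_feed_rate": 0.34,
    "lay_date": 0.04,
    "brood_size": 0.03,
    "fledgling_no": 0.05,
    "fledgling_mass": 0.08,
}


def _diagram(paths) -> PathDiagram:
    lines = [f"{label}: {src} -> {dst}" for label, src, dst, _, _ in paths]
    return parse_diagram("\n".join(lines))


def male_diagram() -> PathDiagram:
    """The 19-path male provisioning model (8 variables)."""
    return _diagram(MALE_PATHS)


def female_diagram() -> PathDiagram:
    """The 14-path female provisioning model (7 variables, no aggression)."""
    return _diagram(FEMALE_PATHS)


def male_coefficients() -> dict[str, float]:
    """Published male point estimates, keyed by path label."""
    return {label: beta for label, _, _, beta, _ in MALE_PATHS}


def female_coefficients() -> dict[str, float]:
    """Published female point estimates, keyed by path label."""
    return {label: beta for label, _, _, beta, _ in FEMALE_PATHS}


def generator_config(
    diagram: PathDiagram,
    coefficients: dict[str, float],
    n_pairs: int,
    *,
    seed: int = 0,
    observation_scale: bool = False,
    repeat_icc: dict[str, float] | None = None,
    stage_effects: dict[str, float] | None = None,
    missing_rates: dict[str, float] | None = None,
) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a diagram and label-keyed
    coefficients (exogenous correlation edges take coefficient 0 unless
    listed by their ``"a<->b"`` key)."""
    edge_coefs = {
        (e.source, e.target): coefficients[e.label] for e in diagram.edges
    }
    exog = {
        (a, b): coefficients.get(f"{a}<->{b}", 0.0) for a, b in diagram.correlations
    }
    exog = {k: v for k, v in exog.items() if v != 0.0}
    return GeneratorConfig(
        n_pairs=n_pairs,
        coefficients=edge_coefs,
        exog_correlations=exog,
        repeat_icc=repeat_icc or {},
        stage_effects=stage_effects or {},
        missing_rates=missing_rates or {},
        observation_scale=observation_scale,
        seed=seed,
    )


def male_generator_config(n_pairs: int = 73, *, seed: int = 0, **kw) -> GeneratorConfig:
    """Male-model study conditions: published coefficients as ground truth.

    Defaults emulate the field study scale (~73 monitored nests); pass a
    larger ``n_pairs`` for parameter-recovery runs. Repeat assays default
    to the published repeatabilities and the nest-stage offsets span the
    incubation-to-nestling contrast controlled for in the aggression assay.
    """
    kw.setdefault(
        "repeat_icc",
        {
            "exploration": EXPLORATION_REPEATABILITY_COMBINED,
            "own_feed_rate": FEEDING_RATE_REPEATABILITY,
            "partner_feed_rate": FEEDING_RATE_REPEATABILITY,
        },
    )
    kw.setdefault("stage_effects", {"nest_building": 0.5, "incubation": 0.2, "nestling": -0.3})
    return generator_config(male_diagram(), male_coefficients(), n_pairs, seed=seed, **kw)


def female_generator_config(n_pairs: int = 73, *, seed: int = 0, **kw) -> GeneratorConfig:
    """Female-model study conditions (no aggression assay)."""
    kw.setdefault(
        "repeat_icc",
        {
            "exploration": EXPLORATION_REPEATABILITY_COMBINED,
            "own_feed_rate": FEEDING_RATE_REPEATABILITY,
            "partner_feed_rate": FEEDING_RATE_REPEATABILITY,
        },
    )
    return generator_config(female_diagram(), female_coefficients(), n_pairs, seed=seed, **kw)
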