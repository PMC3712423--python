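"""Full inference chain on a synthetic breeding season.

Generates a field-scale population (73 pairs, published male-model effect
sizes, realistic per-variable missingness), estimates 1000 posterior
covariance matrices, refits the 19-path male model to every draw and
prints the resulting path table. Coefficients are standardized partial
regression coefficients; 'strong' support means the 95% credible interval
excludes zero, 'some' means it overlaps zero but p < 0.05.
"""

import bayespath as bp

diagram = bp.presets.male_diagram()
cfg = bp.presets.male_generator_config(n_pairs=73, seed=42)
table, truth = bp.generate_population(cfg)
table = bp.apply_missingness(table, bp.presets.FIELD_MISSING_RATES, seed=43)

draws = bp.fit_mvn_missing(table[list(diagram.variables)], seed=44)
coef = bp.propagate(draws, diagram, bp.presets.MALE_COMPOUND_PATHS)
summaries = bp.summarize_all(coef, diagram, bp.presets.MALE_COMPOUND_PATHS,
                             draws.pairwise_n)

frame = bp.report(summaries)
frame["generating"] = [
    truth.coefficients.get((e.source, e.target)) for e in diagram.edges
] + [None] * len(bp.presets.MALE_COMPOUND_PATHS)
print(frame.round(3).to_string(index=False))
print()
print("At 73 pairs the credible intervals are wide: only the larger")
print("generating effects reach 'strong' support, mirroring how a single")
print("field season constrains which hypothesized paths are detectable.")
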