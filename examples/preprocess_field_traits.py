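"""From raw field assays to analysis variables.

Builds observation-scale columns (approach latencies by nest stage,
nest-visit counts per 90-minute window on two days), then derives the
analysis variables: the stage-centred aggression score (box-cox
transformed latency x -1) and the mean feeding rate per hour.
"""

import numpy as np

import bayespath as bp

cfg = bp.presets.male_generator_config(n_pairs=60, seed=5, observation_scale=True)
table, _ = bp.generate_population(cfg)

score = bp.aggression_score(table["latency_s"], table["nest_stage"])
feed = bp.mean_feed_rate(
    table["own_feed_rate_visits_day11"], table["own_feed_rate_visits_day14"]
)

fit = bp.boxcox_transform(table["latency_s"].to_numpy())
print(f"fitted box-cox lambda for latency: {fit.lmbda:.2f}")
for stage in sorted(set(table["nest_stage"])):
    m = table["nest_stage"] == stage
    print(f"  stage {stage:<13} mean score {score[m].mean():+.2e}  (n={m.sum()})")
print(f"mean feeding rate: {feed.mean():.1f} feeds/h (range {feed.min():.1f}-{feed.max():.1f})")
r = np.corrcoef(score, table["aggression"])[0, 1]
print(f"correlation of score with latent aggression: {r:.2f}")
print()
print("Scores are centred within nest stage (means ~0 by construction) and")
print("track the latent aggressiveness despite the nonlinear latency map.")
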