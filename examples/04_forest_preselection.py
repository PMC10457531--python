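"""Rank moderators with a model-based random forest.

Trees with a treatment-effect node model are grown on bootstrap resamples,
each offered a random third of the moderators; permutation importance is
the mean out-of-bag increase in node-model negative log-likelihood when a
moderator's values are shuffled.  Positive importance (or a significant
univariate interaction) selects a moderator for the tree stage.
"""

from hetmob import (ForestConfig, SyntheticConfig, generate_trial_pair,
                    grow_forest, permutation_importance)

table = generate_trial_pair(SyntheticConfig(seed=1))
moderators = ["phq9_baseline", "hamd_baseline", "pseq", "aqol", "odi",
              "nrs_pain", "age", "gender", "sick_leave"]

forest = grow_forest(table, moderators, ForestConfig(n_trees=100, seed=3))
importance = permutation_importance(forest, table)

ranked = importance.table.sort_values("importance", ascending=False)
print(ranked.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\npositive importance: {len(importance.positive())} of {len(moderators)}")

# Symptom-severity scales dominate: they both moderate the planted effects
# and carry prognostic signal the two-arm node model cannot absorb.
# Importances near zero (including negatives) mark moderators the forest
# never found useful.
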