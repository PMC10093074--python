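"""Ground-truthed GA benchmark: recover planted informative features.

Generates a 200-feature table with 20 planted informative columns
(effect size 2.0) and measures how many the GA's best mask recovers.
"""

import numpy as np

from securecnn import GAConfig, PlantedTableConfig, ga_select, gen_planted_table, nb_fitness

table, truth = gen_planted_table(PlantedTableConfig(seed=0))
print(f"table: {table.n_samples} x {table.n_features}, {len(truth)} informative columns")

truth_mask = np.isin(np.arange(table.n_features), truth)
cfg = GAConfig(population=30, max_iterations=50, seed=0)
print(f"fitness of the ground-truth mask: {nb_fitness(table, truth_mask, cfg):.3f}")

result = ga_select(table, cfg)
recovered = np.isin(truth, result.selected_indices).mean()
print(f"GA best mask: fitness {result.best.fitness:.3f}, "
      f"{int(result.best.mask.sum())} features selected, "
      f"recovered {recovered:.0%} of the planted columns")
# A recovery far above the ~50% random-inclusion base rate shows the
# selection pressure is real, not an artifact of mask size.
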