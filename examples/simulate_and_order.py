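"""Recover the temporal order of a shuffled snapshot cohort.

Simulates 12 PSM snapshots of a traveling clock-gene band taken at evenly
spaced (but shuffled) clock phases with 10% noise, then minimizes the
autocorrelation periodicity objective g over permutations by simulated
annealing and scores the result against the known phase order.
"""

import numpy as np

from kymoclock import (
    AnnealConfig,
    WaveModel,
    anneal_order,
    objective_g,
    ordering_distance,
    simulate_cohort,
)

model = WaveModel(mode="band", noise_fraction=0.1, n_bins=100)
cohort = simulate_cohort(model, 12, seed=7, shuffle=True)
matrix = cohort.to_matrix()

state, trace = anneal_order(matrix, config=AnnealConfig(iterations=20000, restarts=5, seed=1))
g_true, _ = objective_g(matrix, cohort.true_order)
distance = ordering_distance(state.permutation, cohort.true_order)

print(f"inferred order (rank -> sample): {[matrix.sample_ids[j] for j in state.permutation]}")
print(f"g(inferred) = {state.objective:.4f}   g(true order) = {g_true:.4f}")
print(f"ordering distance to ground truth = {distance:.4f}")
# The distance is a Kendall disagreement fraction measured after the best
# rotation/reflection (which g cannot resolve); 0 means perfect recovery.
# g(inferred) <= g(true) is expected: noise makes the exact truth slightly
# sub-optimal under the periodicity objective.
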