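"""Predict empirical-format connectivity from a simulated network.

Trains a linear-kernel SVM on one simulated realistic-layout instance
(z-scored |density difference| and distance -> existence), applies it with
dual posterior thresholds to a synthetic macaque-like dataset (1128
directed pairs with an architectonic-type-consistent structure), and
validates accuracy and Youden's J against 100-permutation nulls at each of
the ten thresholds 0.750-0.975.
"""

import numpy as np

import corticodev as cd
from corticodev.connectome import offdiag_mask

layout = cd.get_layout("1D-1row-2or")
result = cd.run_instance(layout, cd.params_for_layout(layout), seed=11)
con = cd.aggregate_connectome(result.synapses, result.neuron_area, result.sheet.n_areas)
m = cd.structural_measures(result.sheet)
mask = offdiag_mask(result.sheet.n_areas)
features = np.column_stack(
    [cd.zscore(m.abs_density_difference[mask]), cd.zscore(m.distance[mask])]
)
classifier = cd.train_classifier(features, con.exists[mask].astype(int))

dataset = cd.generate_fixture(cd.MACAQUE_LIKE, np.random.default_rng(1))
evaluation = cd.evaluate_instance(classifier, dataset, rng=np.random.default_rng(2))

print(f"dataset: {dataset.species_label}, {len(dataset)} directed pairs")
print(f"mean accuracy over thresholds:     {evaluation.mean_accuracy:.3f}")
print(f"mean Youden J over thresholds:     {evaluation.mean_youden:.3f}")
print(f"mean fraction of pairs classified: {evaluation.mean_fraction_classified:.3f}")
print("median permutation-null p-values: ",
      {k: f"{v:.2g}" for k, v in evaluation.median_z_p.items()})

# J well above 0 with vanishing null p-values means the structural
# regularities learned from the simulation transfer to the (synthetic)
# empirical data; a classifier trained on a random-gradient layout instead
# classifies almost no pairs at these confidence thresholds.
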