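"""Train the small multi-channel CNN on nodule patches.

Patches are 21x21x5 HU sub-volumes centred on the consensus centroid,
normalised to [0, 1] with the whole-scan HU extremes; transverse slices
enter the 2-D convolutions as channels.  Training uses shift/rotation/
scale augmentation, an inner 80/20 split, and retains the final weights
plus the three best checkpoints.
"""

from dataclasses import replace

import nodulex as nx
from nodulex import cnn
from nodulex.patches import records_for_selection
from nodulex.pipeline import cohort_consensus

readers = nx.SimulatedReaderSet(4, 0.5, 0.2)
cohort = nx.generate_cohort(
    200, {nx.BENIGN_LIKE: 0.5, nx.MALIGNANT_LIKE: 0.5}, readers, seed=5
)
design = replace(nx.DESIGNS["S12vS45"], seed=5)
selection = nx.select_cohort(cohort_consensus(cohort), design)
train_sel, val_sel = nx.split_train_validation(selection, design)

size = cnn.CNN21.input_size
x_tr, y_tr, _ = cnn.records_to_arrays(
    records_for_selection(train_sel, cohort.volumes, size)
)
x_va, y_va, _ = cnn.records_to_arrays(
    records_for_selection(val_sel, cohort.volumes, size)
)

trained = cnn.train(x_tr, y_tr, cnn.CNN21, nx.TrainConfig(epochs=30, seed=5))
for row in trained.training_log[::5]:
    print(
        f"epoch {row['epoch']:>3}  train loss {row['train_loss']:.3f}  "
        f"inner-test loss {row['test_loss']:.3f}  acc {row['test_accuracy']:.2f}"
    )

scores = cnn.predict(trained, x_va)
result = nx.evaluate(scores, y_va)
features = cnn.extract_features(trained, x_va)
print(f"validation AUC {result.auc:.3f}, accuracy {result.accuracy:.3f}")
print(f"penultimate features per patch: {features.shape[1]}")
print(f"retained checkpoints: {len(trained.retained_checkpoints)} (final + best)")
# The loss should fall over epochs and the validation AUC should be well
# above 0.5: the two phantom classes differ in nodule size and texture.
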