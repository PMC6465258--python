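"""Raw-pixel features plus an rbf-kernel SVM on a small cohort.

Runs the full chain — simulate, normalize, segment, window, scale,
grid-search, train, test — and prints the chosen hyperparameters and
held-out diagnostic performance with Wilson 95% intervals.
"""

import numpy as np

from marrowtex.classify import grid_search_cv, predict, train_svm
from marrowtex.evaluate import confusion_metrics, roc_auc
from marrowtex.featurize import (
    assemble_matrix,
    compute_min_window,
    extract_feature_vector,
    minmax_scale,
)
from marrowtex.orchestrate import preprocess_subject
from marrowtex.phantom import PhantomConfig, generate_cohort

config = PhantomConfig(image_shape=(3, 64, 48))
train = generate_cohort(config, 30, 30, seed=1)
test = generate_cohort(config, 15, 15, seed=2)

prep = [preprocess_subject(r) for r in train + test]
norms, masks = [p[0] for p in prep], [p[1] for p in prep]

spec = compute_min_window(train + test, masks, n_slices=1)
print(f"population-minimal window: {spec.height}x{spec.width} "
      f"-> dimension {spec.dimension}")

vectors = [
    extract_feature_vector(v, r.labels, spec, m, r.subject_id)
    for r, v, m in zip(train + test, norms, masks)
]
y = [r.disease_status for r in train + test]
train_m = assemble_matrix(vectors[:60], y[:60])
test_m = assemble_matrix(vectors[60:], y[60:])
train_s, [test_s] = minmax_scale(train_m, [test_m])

gs = grid_search_cv(train_s, "rbf", C_grid=(0.125, 1, 8, 64),
                    gamma_grid=(2**-7, 2**-5, 2**-3), seed=0)
print(f"grid search: C={gs.best.C:g}, gamma={gs.best.gamma:g} "
      f"(5-fold CV accuracy {gs.best_accuracy:.3f})")

model = train_svm(train_s, gs.best)
pred = predict(model, test_s)
rep = confusion_metrics(pred.labels, test_s.y)
auc, auc_ci = roc_auc(pred.scores, test_s.y)
print(f"test accuracy    {100*rep.accuracy:5.1f}% "
      f"[{100*rep.accuracy_ci[0]:.1f}-{100*rep.accuracy_ci[1]:.1f}]")
print(f"test sensitivity {100*rep.sensitivity:5.1f}% "
      f"[{100*rep.sensitivity_ci[0]:.1f}-{100*rep.sensitivity_ci[1]:.1f}]")
print(f"test AUC         {auc:.3f} [{auc_ci[0]:.3f}-{auc_ci[1]:.3f}]")
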