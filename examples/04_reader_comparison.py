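"""Compare a classifier against simulated human readers.

Simulated readers emit 0-4 confidence scores at a requested
sensitivity/specificity operating point; the comparison statistics are
exactly the ones a diagnostic-accuracy study reports: McNemar on
discordant calls, paired DeLong on AUCs, and Cohen's kappa agreement.
"""

import numpy as np

from marrowtex.evaluate import (
    binarize_scores,
    cohen_kappa,
    compare_auc,
    confusion_metrics,
    mcnemar_test,
    roc_auc,
)
from marrowtex.orchestrate import simulate_readers

rng = np.random.default_rng(0)
truth = np.array([0] * 45 + [1] * 62)  # test-set composition

# a classifier with ~0.9/0.85 operating point, via noisy scores
clf_scores = rng.normal(1.8 * truth - 0.6, 1.0)
clf_calls = (clf_scores > 0).astype(int)

reader = simulate_readers(truth, 0.82, 0.76, seed=1)
reader_calls = binarize_scores(reader)

for name, calls, scores in (
    ("classifier", clf_calls, clf_scores),
    ("reader", reader_calls, reader.astype(float)),
):
    rep = confusion_metrics(calls, truth)
    auc, _ = roc_auc(scores, truth)
    print(f"{name:10s} accuracy {100*rep.accuracy:5.1f}%  "
          f"SE {100*rep.sensitivity:5.1f}%  SP {100*rep.specificity:5.1f}%  "
          f"AUC {auc:.3f}")

kappa = cohen_kappa(clf_calls, reader_calls)
print(f"\nMcNemar p (accuracy difference): "
      f"{mcnemar_test(clf_calls, reader_calls, truth):.3f}")
print(f"DeLong p (AUC difference):       "
      f"{compare_auc(clf_scores, reader.astype(float), truth):.3f}")
print(f"kappa agreement: {kappa.kappa:.3f} ({kappa.band})")
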