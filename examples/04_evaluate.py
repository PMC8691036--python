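"""Score predictions: confusion metrics, ROC/PR AUC, and McNemar's test.

Trains two small models of different capacity on the same data and asks
whether their accuracies differ beyond chance via the continuity-corrected
McNemar test on their discordant predictions.
"""

import numpy as np

from csnet import (
    NetworkConfig, SyntheticSpec, curve_metrics, generate_dataset,
    mcnemar_test, predict, train_ensemble,
)
from csnet.evaluation import report

train, _ = generate_dataset(SyntheticSpec(n_coding=250, n_noncoding=250, seed=3))
test, _ = generate_dataset(SyntheticSpec(n_coding=150, n_noncoding=150, seed=4))
pos = [r for r in train if r.label == "lncRNA"]
neg = [r for r in train if r.label == "mRNA"]

big = train_ensemble(pos, neg, NetworkConfig(n_filters=16, epochs=15, n_ensemble=1, seed=0))
tiny = train_ensemble(pos, neg, NetworkConfig(n_filters=2, hidden_units=4, epochs=2,
                                              n_ensemble=1, seed=0))

y_true = [t.label for t in test]
res_a = predict(big, test)
res_b = predict(tiny, test)

rep = report(y_true, [r.predicted_label for r in res_a])
print("capable model:", {k: round(v, 4) for k, v in rep.items() if k in
                         ("sp", "sn", "acc", "pre", "f1")})
score = big.decision_scores([r.score_pos for r in res_a], [r.score_neg for r in res_a])
roc, pr = curve_metrics(np.array(y_true), score, "lncRNA")
print(f"ROC AUC={roc:.4f}  PR AUC={pr:.4f} (positive class lncRNA)")

corr_a = [r.predicted_label == t for r, t in zip(res_a, y_true)]
corr_b = [r.predicted_label == t for r, t in zip(res_b, y_true)]
mc = mcnemar_test(corr_a, corr_b)
print(f"McNemar: b={mc.b} c={mc.c} chi2={mc.chi2:.3f} p={mc.p_value:.2e}")
print("b/c are the discordant counts (first-correct/second-wrong and the "
      "reverse); a small p says the capacity difference matters.")
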