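"""Paired significance test between two classifier variants.

Fits the scorer twice on the same cohort — once with the 8 leading features
and once with all 20 — and applies McNemar's test to the paired held-out
predictions.  A small p-value means the two panels disagree systematically
on which records they get right; p near 1 means their error patterns are
statistically indistinguishable.
"""

from owod import (
    default_catalog,
    default_synthetic_config,
    fit,
    generate_cohort,
    mcnemar,
    run_config_for,
    train_test_split,
)
from owod.workflow import predict

catalog = default_catalog()
cfg = default_synthetic_config(n_per_class=500, seed=19)
cohort = generate_cohort(cfg)
train, test = train_test_split(cohort, 0.8, seed=19)

order = list(cfg.features)
preds = {}
for size in (8, 20):
    rc = run_config_for(cfg, features=order[:size], seed=19)
    model = fit(train, rc, catalog)
    preds[size] = predict(model, test)["predicted"].to_numpy()

actual = test.labels.to_numpy()
stat, p = mcnemar(preds[8], preds[20], actual)
acc8 = (preds[8] == actual).mean()
acc20 = (preds[20] == actual).mean()
print(f"accuracy: 8 features {acc8:.4f}, 20 features {acc20:.4f}")
print(f"McNemar statistic {stat:.4f}, p = {p:.4g}")
print("significant at p < 0.01" if p < 0.01 else "not significant at p < 0.01")
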