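"""Full synthetic benchmark: generate a database, fit DOP thresholds, and
rank the simulated predictors.

Generates a 199-record curated-style database (129 immunogenic / 70 not) and
a 120-pair validation set, scores both with binormal predictors whose target
AUCs sit in the weak 0.52-0.60 regime, fits each predictor's DOP-minimizing
threshold on the database, freezes it, and assembles the full rank table.
"""

import pandas as pd

import neobench as nb
from neobench.simulate import SimulationConfig, default_method_specs

cfg = SimulationConfig(seed=7)
records = nb.simulate_database(cfg)
db_scores = nb.simulate_scores(records, cfg)
pairs, val_scores = nb.simulate_validation_set(cfg)

db_labels = {r.record_id: r.label for r in records}
val_labels = {p.pair_id: p.label for p in pairs}

rows = []
for spec in default_method_specs(cfg):
    db = db_scores.slice(spec)
    db["label"] = db["record_id"].map(lambda r: db_labels[r].value)
    val = val_scores.slice(spec)
    val["label"] = val["record_id"].map(lambda r: val_labels[r].value)
    rows.append(nb.evaluate_method(db, val, spec))

table = nb.aggregate_ranks(pd.DataFrame(rows))
cols = ["method", "metric", "dop", "f1", "auc", "fpr", "fnr", "ar", "ar_sd"]
print(table[cols].round(3).to_string(index=False))
# DOP near 0.8-1.0 and AUCs barely above 0.5 are what weak predictors look
# like on this problem; the AR ordering is how a winner is still declared.
print(f"\ntop performer on this draw: {table.iloc[0]['method']} "
      f"({table.iloc[0]['metric']}), AR={table.iloc[0]['ar']:.2f}")
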