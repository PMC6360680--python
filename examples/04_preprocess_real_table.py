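"""Preprocess a raw delimited feature table and select features on it.

Mirrors the standard LC-MS workflow: read a table with missing cells,
average technical duplicates per biological unit, drop features missing
in >= 30% of units, zero-impute the rest, then fit and select.
"""

import tempfile
from pathlib import Path

import numpy as np

from bcrange import (
    SelectionParams,
    fit_biplot,
    preprocess,
    read_feature_table,
    select_features,
)
from bcrange.tableio import write_selection

rng = np.random.default_rng(3)
n_units, n_feat = 24, 40
lines = ["sample,label," + ",".join(f"m{j}" for j in range(n_feat))]
for u in range(n_units):
    label = u % 2
    base = rng.lognormal(3, 0.4, n_feat)
    base[:4] *= 1.0 + 2.0 * label  # four truly different features
    for rep in ("a", "b"):  # two technical replicates per unit
        vals = base * rng.lognormal(0, 0.05, n_feat)
        cells = [f"{v:.3f}" if rng.random() > 0.05 else "na" for v in vals]
        lines.append(f"u{u}{rep},{label}," + ",".join(cells))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "intensities.csv"
    path.write_text("\n".join(lines) + "\n")

    raw = read_feature_table(path, label_col="label")
    raw.replicate_map = {sid: sid[:-1] for sid in raw.sample_ids}
    print(f"read {len(raw.sample_ids)} rows x {len(raw.feature_ids)} features")

    table = preprocess(raw, max_missing_frac=0.30)
    print(f"after preprocessing: {table.n_samples} units x "
          f"{table.n_features} features")

    model = fit_biplot(table, autoscale=True)
    result = select_features(model, table, SelectionParams(tau=0.15,
                                                           autoscale=True))
    ids = [table.feature_ids[j] for j in sorted(result.union_selected)]
    print(f"selected {len(ids)} features: {', '.join(ids)}")

    report = Path(tmp) / "selection.tsv"
    write_selection(result, report, feature_ids=table.feature_ids)
    print(f"per-group report has {sum(1 for _ in open(report)) - 1} rows")
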