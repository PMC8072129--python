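"""Median imputation stratified by (age bin, sex).

Analyte levels differ by demographic group, so missing cells are filled
with the median of patients in the same (ChiMerge age bin, sex) cell,
falling back to the sex-level and then global median when a cell was
empty in training.
"""

from fldscreen import (CohortConfig, apply_imputer, fit_chimerge,
                       fit_imputer, simulate_cohort)
from fldscreen.prep import PrepConfig, drop_sparse_features, filter_unlabeled
from fldscreen.tables import feature_columns, labels

table = filter_unlabeled(simulate_cohort(CohortConfig(n_samples=6000, seed=11)))
table, dropped = drop_sparse_features(table, PrepConfig())
print("dropped near-empty columns:", dropped)

scheme = fit_chimerge(table["age"].to_numpy(dtype=float), labels(table), 5)
plan = fit_imputer(table, scheme)

print("\nGGT medians by (age bin, sex)  [men run higher, levels rise with age]:")
for b, interval in enumerate(scheme.intervals()):
    row = [f"{plan.group_medians.get((b, s), {}).get('GGT', float('nan')):6.1f}"
           for s in (0, 1)]
    print(f"  {interval:>14s}:  women {row[0]}   men {row[1]}")

before = table[feature_columns(table)].isna().sum().sum()
filled = apply_imputer(plan, table)
after = filled[feature_columns(filled)].isna().sum().sum()
print(f"\nmissing cells before: {before},  after imputation: {after}")
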