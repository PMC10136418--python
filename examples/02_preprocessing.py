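"""Missing-value filters and iterative forest imputation.

Injects MCAR missingness into a synthetic cohort at per-patient rates
calibrated so about a quarter of patients exceed the 40% cut-off, then
runs the ordered preprocessing pipeline: patient filter, feature filter,
MissForest-style imputation.
"""

import tinnibench as tb

spec = tb.make_reference_spec(n_patients=800)
table, _, _ = tb.generate_cohort(spec, seed=0)
holed = tb.inject_missingness(table, spec, seed=1)
print(f"injected missingness: {100 * holed.missing_mask.to_numpy().mean():.1f}%"
      " of cells masked")

filtered = tb.filter_patients(holed, max_missing=0.40)
print(f"patient filter (>40% missing removed): kept"
      f" {filtered.n_patients}/{holed.n_patients}"
      f" ({100 * filtered.n_patients / holed.n_patients:.1f}%)")

filtered = tb.filter_features(filtered, max_missing=0.25)
print(f"feature filter (>25% missing removed): kept"
      f" {filtered.data.shape[1]}/{holed.data.shape[1]} features")

imputed = tb.impute_iterative_forest(filtered, seed=2, n_trees=30)
print(f"after imputation: {int(imputed.missing_mask.to_numpy().sum())}"
      " missing cells remain (random forests per feature, iterated until"
      " the imputed values stop changing)")
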