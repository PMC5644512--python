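"""Tiny end-to-end run of the stepwise one-vs-one SVM protocol.

Generates a small 7-class dataset, balances it with ADASYN, runs the
multi-restart stepwise-SVM evaluation on the full feature model, and
reports the cross-validated multiclass accuracy.  Problem sizes are kept
small so the script finishes in about a minute.
"""

import warnings

from chromatex import analysis, generate_class_dataset, pipeline

warnings.simplefilter("ignore")

_, table = generate_class_dataset(n_per_class=8, seed=1)
norm = analysis.normalize_features(table)
balanced = pipeline.adasyn_balance(norm, per_class_target=16, seed=2)
print(f"{len(table)} nuclei extracted, balanced to {len(balanced)} rows")

result = pipeline.evaluate(
    balanced, pipeline.FEATURE_FAMILIES["Pf.A"],
    restarts=2, mcv_repeats=3, folds=3, seed=4,
)
print(f"best restart: {result.best_index + 1}, "
      f"accuracy {result.average:.2f}% +/- {result.sd:.2f}%")
pair, model = next(iter(result.best_models.models.items()))
print(f"example pair {pair}: kernel={model.kernel}, C={model.cost}, "
      f"features={model.features}")
print("accuracy is the one-vs-one majority-vote CV accuracy over the")
print("21 class pairs, maximized over restarts of the stepwise selection.")
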