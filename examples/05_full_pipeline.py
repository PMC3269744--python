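"""The end-to-end workflow: simulate -> select -> fit -> validate -> interpret.

Runs the whole pipeline from a config dictionary, prints the selection
summary, the kernel comparison, the external-validation metrics with
the R^2_pred > 0.6 acceptability rule, and the published comparator
table shipped with the package.
"""

import svrqsar as q

report = q.run_pipeline({
    "synthetic": {"n": 40, "D": 60, "k": 5, "r": 1, "rho": 0.85,
                  "n_constant": 3, "noise_sd": 0.25, "effect": "linear",
                  "seed": 5},
    "seed": 5,
})

print(f"retained {len(report.retained)} descriptors: {report.retained}")
print("\nkernel comparison (LOO CV MSE on the retained set):")
for label, mse in report.kernel_cv.items():
    marker = "  <- chosen" if label == report.chosen_kernel else ""
    print(f"  {label:10s} {mse:8.3f}{marker}")

test = report.evaluation["test"]
print(f"\nexternal test set (n={test['n']}):")
print(f"  MSE      = {test['mse']:.3f}")
print(f"  R^2      = {test['r2']:.3f}")
print(f"  R^2_pred = {test['r2_pred']:.3f}  (acceptable if > 0.6: "
      f"{report.acceptable})")

print("\nliterature comparators (ARC-111 analogue series, test-set values):")
for row in report.literature_comparators:
    print(f"  {row['model']:13s} MSE {row['mse']:.3f}  R2 {row['r2']:.3f}  "
          f"R2_pred {row['r2_pred']:.3f}")
# The comparator rows are published reference values for the same kind
# of workflow on the real compound series; they are displayed for
# context, not recomputed (the underlying descriptor values were never
# published).
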