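"""Run the full guardrail analysis: base case plus sensitivity grids.

Simulates a cohort, injects 7.5% novice biometry error, calibrates
discrepancy thresholds on the tuning split to capture 80/90/95% of gross
errors (novice GA at least 10 days from the expert's), and evaluates the
cut-points on the test split.
"""

from fetalqc.cohort import CohortConfig
from fetalqc.experiments import ExperimentConfig, run_base_case, run_sensitivity_grid

config = ExperimentConfig(
    cohort=CohortConfig(n_participants=5000, seed=0),
    model_degradation_factor=1.1,
    master_seed=1,
)

base = run_base_case(config)
print("operating points (test split):")
for target, result in base.guardrail.items():
    s, s_lo, s_hi = result.sensitivity
    p, p_lo, p_hi = result.specificity
    print(
        f"  capture {target:.0%} of gross errors -> threshold "
        f"{base.thresholds[target]:.1f} d: sensitivity {s:.1%} ({s_lo:.1%}, {s_hi:.1%}), "
        f"specificity {p:.1%} ({p_lo:.1%}, {p_hi:.1%})"
    )
auc, lo, hi = next(iter(base.guardrail.values())).auc
print(f"  AUC {auc:.2f} (95% CI {lo:.2f}, {hi:.2f})")

print("\nAUC over (gross-error definition) x (novice error level):")
for factor, grid in run_sensitivity_grid(config).items():
    label = "full-quality model" if factor == 1.0 else f"degraded model (x{factor})"
    print(f"-- {label}")
    print(grid.auc.round(2).to_string())
# Thresholds fall as the capture target rises; AUC rises with more novice
# error or a looser gross-error definition, and falls for a degraded model.
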