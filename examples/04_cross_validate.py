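"""Estimate prediction accuracy by repeated two-fold cross-validation.

Runs the sweep protocol with fixed pipeline parameters on a small synthetic
dataset and reports sensitivity/specificity with standard deviations, plus
the full per-configuration grid table.
"""

from scamix import (CVGrid, SimulationConfig, grid_report,
                    repeated_two_fold_cv, simulate_dataset)

config = SimulationConfig(n_features=3000, n_disease=25, n_control=25, seed=3)
dataset, _ = simulate_dataset(config)

grid = CVGrid(M_values=(2, 3), delta_theta_values=(3.0,),
              lambda_multipliers=(1e-6,), n_outer_repetitions=5, seed=11)
report = repeated_two_fold_cv(dataset, grid, mode="sweep")

print(f"sensitivity {report.mean_sensitivity:.3f} "
      f"(sd {report.sd_sensitivity:.3f})")
print(f"specificity {report.mean_specificity:.3f} "
      f"(sd {report.sd_specificity:.3f})")
print(f"accuracy    {report.mean_accuracy:.3f}")
print(f"winning configuration: {report.winning_config}")
print()
print("per-configuration sweep (best first):")
print(grid_report(report.grid_records).to_string(index=False))
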