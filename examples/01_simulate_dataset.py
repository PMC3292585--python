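"""Generate a synthetic validation dataset of orthogonal mixed components.

Builds 10 orthogonal components over 3000 features, draws per-sample mixing
angles from the role-specific sectors and mixes them into 20 disease and 20
control samples with sin^2/cos^2 weights.
"""

import numpy as np

from scamix import SimulationConfig, simulate_dataset

config = SimulationConfig(n_features=3000, n_disease=20, n_control=20, seed=42)
dataset, truth = simulate_dataset(config)

print(f"dataset: {dataset.n_samples} samples x {dataset.n_features} features")
print(f"labels: {np.sum(dataset.labels == 1)} disease, "
      f"{np.sum(dataset.labels == -1)} control")
print(f"component roles: {truth.roles}")
sizes = [len(s) for s in truth.supports]
print(f"support sizes (disjoint): {sizes}")

# each component's concentration is split between the two class rules;
# the two weights always sum to one per (sample, component)
theta = np.radians(truth.angles)
total = np.sin(theta) ** 2 + np.cos(theta) ** 2
print(f"max |sin^2 + cos^2 - 1| = {np.abs(total - 1).max():.2e}  (conservation)")

# disease-role angles live in the [50, 89.99] degree sector, so the
# disease component carries more weight in disease samples
w_dis = np.sin(theta[:20, 0]) ** 2   # disease rule, disease-role component
w_con = np.cos(theta[20:, 0]) ** 2   # control rule, same component
print(f"mean disease-component weight: {w_dis.mean():.2f} in disease samples, "
      f"{w_con.mean():.2f} in control samples")
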