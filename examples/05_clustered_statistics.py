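"""Cluster-aware inference on simulated paired eye data.

Participants contribute two eyes, so observations are correlated within
participant; all CIs below resample participants (clusters), not eyes.
"""

import numpy as np

from npabench import (
    auroc, delong_test, first_scan_filter, icc_agreement, pearson_clustered,
    spearman_diff, spearman_rho,
)

rng = np.random.default_rng(0)
m = 120                                   # participants
u = rng.normal(0, 0.8, m)                 # participant effect
severity = rng.integers(0, 4, m)          # shared by both eyes
x = np.repeat(u + 0.5 * severity, 2) + rng.normal(0, 0.5, 2 * m)  # method A
y = 0.8 * x + rng.normal(0, 0.4, 2 * m) - 0.3                     # method B
sev = np.repeat(severity, 2)
cid = np.repeat(np.arange(m), 2)

r = pearson_clustered(x, y, cid, n_boot=2000, seed=1)
print(f"Pearson r between methods: {r.estimate:.3f} "
      f"(95% CI {r.ci_low:.3f} to {r.ci_high:.3f}, "
      f"{r.n_units} eyes / {r.n_clusters} participants)")

icc = icc_agreement(x, y, cid, n_boot=2000, seed=2)
print(f"ICC(A,1):                  {icc.estimate:.3f} "
      f"(95% CI {icc.ci_low:.3f} to {icc.ci_high:.3f})")
print("  (lower than r: absolute agreement penalizes method B's offset)")

rho_a = spearman_rho(x, sev).estimate
rho_b = spearman_rho(y, sev).estimate
d = spearman_diff(x, y, sev, cid, n_boot=2000, seed=3)
print(f"Spearman vs severity:      A {rho_a:.3f}, B {rho_b:.3f}, "
      f"diff {d.estimate:.3f} (p={d.p_value:.3f})")

labels = sev >= 2
a_auc = auroc(x, labels, cid, n_boot=2000, seed=4)
dl = delong_test(x, y, labels)
print(f"AUROC (A, staging):        {a_auc.estimate:.3f} "
      f"(95% CI {a_auc.ci_low:.3f} to {a_auc.ci_high:.3f})")
print(f"DeLong A vs B:             diff {dl.estimate:+.3f}, p={dl.p_value:.3f}")
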