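"""Train the learned two-channel segmenter and compare against an
angio-only ablation on shadowed regions.

Shadow artifacts mimic nonperfusion in the angiographic channel; the
structural channel disambiguates (low angio + low structure = shadow, low
angio + high structure = true nonperfusion).
"""

import numpy as np

from npabench import CohortConfig, SegmenterConfig, generate_cohort, train_segmenter


def dice(a, b):
    s = a.sum() + b.sum()
    return 2 * (a & b).sum() / s if s else 1.0


train_cfg = CohortConfig(n_participants=15, eyes_per_participant=2, seed=11, id_prefix="TR")
test_cfg = CohortConfig(n_participants=5, eyes_per_participant=2, seed=12, id_prefix="TE")
test_cfg.shadow_model = dict(test_cfg.shadow_model, prob=0.8)

train_records, train_table = generate_cohort(train_cfg)
test_records, test_table = generate_cohort(test_cfg)
train = [train_records[i] for i in train_table[train_table["slab"] == "SVC"]["scan_index"]]
test = [test_records[i] for i in test_table[test_table["slab"] == "SVC"]["scan_index"]]

model = train_segmenter(train, SegmenterConfig(seed=0))
ablation = train_segmenter(train, SegmenterConfig(seed=0, use_structure=False))

scores, sh2, sh1 = [], [], []
for scan, truth in test:
    _, mask2 = model.segment(scan)
    _, mask1 = ablation.segment(scan)
    scores.append(dice(mask2.mask, truth.npa_mask))
    sh = truth.shadow_mask
    if sh.sum() > 500:
        sh2.append((mask2.mask[sh] == truth.npa_mask[sh]).mean())
        sh1.append((mask1.mask[sh] == truth.npa_mask[sh]).mean())

print(f"trained on {len(train)} scans; held-out Dice {np.mean(scores):.3f}")
print(f"shadow-pixel accuracy: two-channel {np.mean(sh2):.3f} "
      f"vs angio-only {np.mean(sh1):.3f}")
# The two-channel model stays accurate inside shadows; the ablation
# misclassifies shadowed perfused retina as nonperfusion.
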