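"""Generate a small synthetic OCTA cohort and inspect its design.

Each eye gets per-plexus vessel networks with a foveal avascular zone,
severity-dependent nonperfusion lesions, and per-visit angio/structure image
pairs with SSI-dependent noise and occasional shadow artifacts.
"""

from npabench import CohortConfig, generate_cohort

cfg = CohortConfig(n_participants=4, eyes_per_participant=2, visits_per_eye=2, seed=7)
records, table = generate_cohort(cfg)

print(f"{len(records)} scan records "
      f"({cfg.n_participants} participants x 2 eyes x 2 visits x 4 slabs)")
print()
print(table[["participant_id", "eye_id", "visit_index", "slab", "etdrs",
             "severity_group", "ssi", "true_npa_mm2"]].head(12).to_string())

scan, truth = records[0]
print()
print(f"first scan: slab={scan.slab.value}, SSI={scan.ssi:.1f}, "
      f"ETDRS={scan.etdrs}")
print(f"  vessel density        {truth.vessel_mask.mean():.3f}")
print(f"  true NPA              {truth.npa_mask.sum() * scan.pixel_pitch_mm**2:.3f} mm^2")
print(f"  shadowed pixels       {truth.shadow_mask.sum()}")
# true_npa_mm2 includes the foveal avascular zone (~0.3 mm^2) plus lesions;
# severity group drives the expected lesion burden.
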