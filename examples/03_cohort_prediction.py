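"""Desk-scale two-group study: detect and localize a texture effect.

Simulates a 50-subject cohort whose group B carries a mean-preserving
noise-variance inflation in one parcel, then compares per-parcel
radiomic features against the classic 100-point mean profile with a
repeated leave-one-out random forest.  The profile is blind to
mean-preserving changes; the radiomic features are not.

Runs a trimmed configuration (3 seeds, 200 trees) so it finishes in a
couple of minutes.
"""

import numpy as np

import radtract as rt

phantom = rt.PhantomSpec(
    shape="tube", length=48.0, radius=3.0, n_streamlines=100,
    jitter=0.2, grid_shape=(26, 26, 58), seed=21,
)
cohort = rt.CohortSpec(
    n_per_group=25, effect="texture", rho=2.0, effect_parcel=3,
    n_parcels=8, seed=5,
)
result = rt.run_cohort_experiment(
    phantom, cohort, subset="original", n_seeds=3, n_trees=200, base_seed=0
)

rad = result.radtract_report
prof = result.profile_report
print(f"radiomic features : AUROC {rad.mean_score:.3f} +/- {rad.sd_score:.3f}")
print(f"profile baseline  : AUROC {prof.mean_score:.3f} +/- {prof.sd_score:.3f}")
print(f"injected parcel   : {result.injected_parcel}")
print("parcel importance :")
for parcel, imp in result.parcel_importance.sort_values(ascending=False).items():
    print(f"  {parcel}: {imp:.3f}")
print(f"top parcel per seed: {result.per_seed_top_parcel}")
print("AUROC 0.5 is chance; the importance map should single out the")
print("parcel carrying the injected variance change.")
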