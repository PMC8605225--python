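"""End-to-end synthetic study: phantom cohort -> agreement report.

Simulates a small cohort (3 patients x 4 raters) of phantom pelvic
anatomies with the default rater-noise model on a coarsened lattice, runs
the full agreement study and prints the median (IQR) report table.
"""

import concord as cc

# same physical anatomy as the default study, voxelized at 2 mm isotropic
# so the example runs in a few seconds
grid = cc.default_grid(dims=(60, 60, 64), spacing=(2.0, 2.0, 2.0))

cohort = cc.simulate_cohort_masks(
    n_patients=3,
    n_raters=4,
    master_seed=42,
    base_spec=cc.default_phantom(grid),
)
result = cc.run_agreement_study(cohort)
print(f"{len(result.records)} pair records "
      f"({result.n_raters} raters -> 6 pairs x {result.n_patients} patients "
      f"per structure), {len(result.failures)} failures\n")

summary = cc.build_report(result)
print(cc.render_report_text(summary))

# Each column is a structure (the NVB columns are joined by their derived
# inferior-half subsets); each row a metric summarized as median (q1 - q3)
# over all rater pairs and patients.  With the default noise model the
# large prostate keeps a high Dice while the small tubular structures sit
# in the mid range, and the inferior-half NVB agrees better than the whole
# NVB because the noise model diverges toward the superior end --- the
# pattern the pipeline is designed to expose.  The prostate's border
# distance reads NA because it is never cropped.
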