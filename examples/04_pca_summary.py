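"""Principal components of the proteome and the PC1-gestational age link.

With module latent factors strongly tied to gestational age (a deliberate
construction), the leading component of the standardized log2 matrix
tracks gestational age closely — the unsupervised structure the study's
first figure displays.
"""

import afproteome as afp

cfg = afp.SimConfig(seed=3, module_ga_weight=0.9)
matrix, metadata, annotation, truth = afp.simulate_cohort(cfg)
norm, _ = afp.normalize_chain(
    matrix, annotation,
    control_reference=truth.reference, calibrator_reference=truth.reference,
    plate_ids=metadata.table["plate_id"], calibrators=truth.calibrators,
    log2=True,
)
pca = afp.compute_pca(norm.subset(analytes=annotation.assay_ids), n_components=3)

for i, frac in enumerate(pca.variance_fraction, start=1):
    print(f"PC{i}: {100 * frac:.1f}% of variance")

r, p = afp.pc_trait_correlation(
    pca.scores["PC1"].to_numpy(),
    metadata.table["gestational_age_weeks"].to_numpy(),
)
print(f"\nPC1 vs gestational age: |r| = {abs(r):.3f} (p = {p:.2e})")
print("a |r| close to 1 means the dominant axis of proteome variation is "
      "gestational age itself")
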