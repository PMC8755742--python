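"""Moderated differential abundance with covariate adjustment.

Per-analyte linear models (group + fetal sex + maternal age) with
empirical-Bayes variance shrinkage; calls require q < 0.1 and fold change
>= 1.5.  The generator plants 25% true effects, so the call list can be
scored against the truth.
"""

import numpy as np

import afproteome as afp

cfg = afp.SimConfig(seed=2)
matrix, metadata, annotation, truth = afp.simulate_cohort(cfg)
norm, _ = afp.normalize_chain(
    matrix, annotation,
    control_reference=truth.reference, calibrator_reference=truth.reference,
    plate_ids=metadata.table["plate_id"], calibrators=truth.calibrators,
    log2=True,
)
assay = norm.subset(analytes=annotation.assay_ids)

de = afp.run_differential_abundance(assay, metadata)
print(f"variance prior: d0 = {de.attrs['d0']:.2f}, s0^2 = {de.attrs['s0_sq']:.3f}")
print(f"called significant: {int(de['significant'].sum())} of {len(de)} "
      f"({de.attrs['n_up']} up, {de.attrs['n_down']} down at term)")

called = de.index[de["significant"]]
fdr = 1 - truth.analytes.loc[called, "is_de"].mean()
print(f"empirical FDR against the planted truth: {fdr:.3f} (target < 0.1)")

top = de[de["significant"]].sort_values("fold_change", ascending=False).head(5)
print("\nlargest fold changes (unsigned, with direction):")
for aid, row in top.iterrows():
    print(f"  {aid}  {row['fold_change']:6.2f}-fold {row['direction']:<5} "
          f"q = {row['q']:.2e}")

# sensitivity analysis: adding a BMI covariate barely moves the estimates
with_bmi = afp.run_differential_abundance(
    assay, metadata, covariates=("fetal_sex", "maternal_age_years", "bmi_kg_m2")
)
r, agree = afp.compare_adjustments(de, with_bmi)
print(f"\nBMI-adjustment sensitivity: fold-change correlation r = {r:.4f}, "
      f"direction agreement = {100 * agree:.0f}% over the called set")
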