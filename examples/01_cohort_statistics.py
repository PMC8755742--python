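"""Cohort demographics: Fisher's exact test on published contingency tables.

The categorical cohort comparisons (rows: term-not-in-labor n=13,
midtrimester n=15; columns: yes/no) are reproducible from the printed
counts alone.  Each p-value is the two-sided point-probability Fisher
exact test; p < 0.05 marks a covariate imbalanced between groups (such
covariates enter the differential-abundance models as adjustments).
"""

import afproteome as afp

tables = {
    "African-American race": ((10, 3), (13, 2)),
    "Smoking": ((3, 10), (1, 14)),
    "Nulliparity": ((2, 11), (2, 13)),
    "History of preterm birth": ((2, 11), (0, 15)),
    "Cesarean delivery": ((12, 1), (6, 9)),
    "Female fetus": ((2, 11), (9, 6)),
}

print(f"{'variable':<28}{'p (Fisher, two-sided)':>22}")
for name, table in tables.items():
    p = afp.fisher_exact_2x2(table)
    flag = "  *" if p < 0.05 else ""
    print(f"{name:<28}{p:>22.3f}{flag}")
print("\n* imbalanced between gestational-age groups at p < 0.05")

# Welch's t-test for a continuous variable on synthetic metadata
_, metadata, _, _ = afp.simulate_cohort(afp.SimConfig(seed=0))
mid = metadata.table.query("group == 'midtrimester'")["maternal_age_years"]
term = metadata.table.query("group == 'term'")["maternal_age_years"]
t, df, p = afp.welch_t_test(term, mid)
print(f"\nsynthetic maternal age, term vs midtrimester: "
      f"t = {t:.2f}, df = {df:.1f}, p = {p:.3f}")
print("(simulated ages are drawn from one distribution, so p is typically large)")
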