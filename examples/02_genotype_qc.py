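"""Genotype quality control on a cohort with missing calls.

Runs the full QC chain — call-rate filters, LD-proxy replacement of
missing calls, exact Hardy-Weinberg test in controls, MAF floor — then
ancestry correction and the diagnosis-based pre-filter that reduces the
panel before decomposition.
"""

from picalink import (
    SyntheticConfig,
    ancestry_correct,
    generate_linked_dataset,
    hwe_test,
    prefilter_group_difference,
    run_qc,
)

cfg = SyntheticConfig(seed=4, n_voxels=300, n_snps=400, missing_rate=0.002)
_, geno, cov, _ = generate_linked_dataset(cfg)
controls = cov.loc[cov["diagnosis"] == 0, "id"].tolist()

table, reports = run_qc(geno, controls)
for r in reports:
    print(f"{r.step:>10}: -{r.n_subjects_removed} subjects, "
          f"-{r.n_snps_removed} SNPs")
print(f"clean table: {table.n_subjects} subjects x {table.n_snps} SNPs, "
      f"no missing calls")

# the exact HWE test: a perfectly equilibrated table is not rejected,
# an all-heterozygote one overwhelmingly is
print(f"HWE p (25/50/25) = {hwe_test(25, 50, 25):.3f};"
      f" HWE p (0/100/0) = {hwe_test(0, 100, 0):.2e}")

dosage, removed_pcs = ancestry_correct(table.to_modality_matrix(),
                                       cov["ethnicity"].to_numpy())
selected = prefilter_group_difference(dosage, cov["diagnosis"].to_numpy(),
                                      alpha=0.01)
# the generator assigns ethnicity labels independently of the genotypes,
# so no dosage PC should associate with them here
print(f"ethnicity-associated PCs removed: {removed_pcs}")
print(f"pre-filter kept {len(selected)} of {table.n_snps} SNPs at p < 0.01")
# Kept SNPs are the markers weakly separating patients from controls —
# the reduced panel the decomposition consumes.
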