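"""Generate a linked two-modality cohort and recover the planted pair.

Builds a 160-subject cohort (73 patients / 87 controls, 4 sites) whose FA
and SNP loadings share one correlated component pair (r = -0.37), removes
site effects, runs the constrained parallel decomposition, and scores how
well the planted structure was recovered.
"""

import numpy as np

from picalink import (
    DecompositionConfig,
    SyntheticConfig,
    generate_linked_dataset,
    regress_out_site,
    run_parallel_ica,
    score_recovery,
)

fa, geno, cov, truth = generate_linked_dataset(SyntheticConfig(seed=1))
print(f"cohort: {fa.n_subjects} subjects, {fa.n_variables} voxels, "
      f"{geno.n_snps} SNPs; planted loading corr = {truth.linked_corr:+.2f}")

fa_corrected = regress_out_site(fa, cov["site"].to_numpy())
result = run_parallel_ica(fa_corrected, geno.to_modality_matrix(),
                          DecompositionConfig(seed=2))
i, j, r = result.top_pair()
report = score_recovery(result, truth)

print(f"top loading pair: FA component {i} x SNP component {j}, r = {r:+.3f}")
print(f"planted pair matched: {report.pair_matched}; sign-aligned estimate "
      f"= {report.estimated_pair_corr_aligned:+.3f}")
print("per-component recovery |corr|, FA:",
      np.round(report.fa_recovery, 2))
# The matched estimate should sit near the planted -0.37 (the constraint
# enhances the pair slightly); FA component recovery near 1.0 means the
# spatial maps were separated essentially perfectly.
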