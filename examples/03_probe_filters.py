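"""Flag SNP-confounded probes and subtract a confounder DML list.

A probe whose per-sample β values cluster at ~0 / 0.5 / 1 shows an allelic
pattern indistinguishable from a SNP rather than a methylation difference;
the manifest's known-SNP column and an external confounder contrast
(e.g. an infection-status DML list) supply two further exclusion flags.
"""

import monomethir as mm

cohort = mm.simulate_cohort(seed=7)
truth = cohort.truth

flags = mm.snp_pattern_flags(cohort.beta)
snp_like = truth["is_snp_like"]
print(f"trimodal pattern filter: flags {flags[snp_like].mean():.0%} of the "
      f"{int(snp_like.sum())} SNP-like probes, "
      f"{flags[truth['is_planted_dml']].mean():.1%} of planted DMLs")

# a hand-made trimodal row, and a hemimethylated one the filter must spare
print("hand-made trimodal row flagged:",
      mm.snp_pattern_flag([0.02, 0.49, 0.98, 0.51, 0.01, 0.97]))
print("hemimethylated row flagged:   ",
      mm.snp_pattern_flag([0.50, 0.52, 0.48, 0.51, 0.49, 0.50]))

# confounder subtraction at the study's printed scale: 162 DMLs, 5 shared
primary = [f"cg{i:05d}" for i in range(162)]
retained, overlap, pct = mm.confound_overlap_filter(primary, primary[:5] + ["other"])
print(f"confounder overlap: {len(overlap)} of {len(primary)} ({pct}%) removed, "
      f"{len(retained)} retained")
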