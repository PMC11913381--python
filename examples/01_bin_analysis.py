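"""Replication-timing bin analysis of a UV-like mutation call set.

Simulates a repair-proficient study (~12,000 substitutions with an 8%
excess of mutations in early-replicating DNA), partitions the genome into
equal-sequence early/middle/late bins, and compares observed counts to
trinucleotide-composition expectations.
"""

import dataclasses

import reptimemut as rm

cfg = rm.SimConfig(seed=42, repeat_region=None)
genome = rm.gen_genome(cfg)
tmap = rm.gen_timing_map(cfg, genome)
bins = rm.compute_bins(tmap)

# an 8% early excess corresponds to a negative log-linear timing effect
beta = rm.beta_for_contrast(-0.08, tmap, bins)
records, _ = rm.gen_mutations(dataclasses.replace(cfg, timing_effect=beta),
                              genome, tmap)

res = rm.run_mutation_analysis(genome, tmap, records, bins=bins)["unmasked"]

print(f"tercile cutpoints: {bins.cut_early_mid:.2f} / {bins.cut_mid_late:.2f} min")
print(res.bin_table.to_frame().round(1))
print(f"chi-square GOF: stat={res.chisq.statistic:.2f} p={res.chisq.p_value:.3g}")
r = res.regression.estimates
print(f"nine-bin regression: slope={r['slope']:.1f}/min, "
      f"Pearson r={r['r']:.2f}, p={res.regression.p_value:.3g}")

# The bin table shows more observed mutations in the early tercile than in
# the late one, while the composition-based expectations are nearly flat:
# the chi-square p-value and the negative nine-bin slope quantify how
# strongly mutation load tracks replication time.
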