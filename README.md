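# reptimemut

Replication-timing analysis of UV-induced mutagenesis and CPD damage
maps in budding yeast.

UV light forms cyclobutane pyrimidine dimers (CPDs) at adjacent
pyrimidines; unrepaired lesions are bypassed by error-prone translesion
synthesis and become mutations. Whether a locus replicates early or late
in S-phase shapes both its damage burden and its mutation rate. This
package provides the full analysis stack for asking that question from
standard files — mutation call tables, a replication-timing anchor map,
genome FASTA, CPD-seq wiggle tracks, a signature catalogue:

* **Timing assignment** — linear interpolation of replication time
  (minutes in S-phase) at any position from ~500-bp anchors:
  `time = time1 + (time2 − time1)·(pos − pos1)/(pos2 − pos1)`; uncovered
  positions are excluded, never extrapolated.
* **Equal-sequence bins** — early/middle/late terciles (and nine nested
  sub-bins) each covering a third of the mapped genome, cut on the
  pooled, span-weighted interval times.
* **Composition expectations** — per-bin expected mutation counts from
  the 96-channel trinucleotide census of each bin
  (E_bin = Σ_c r_c·census_bin[t(c)], rates estimated genome-wide), with
  chi-square goodness of fit and a nine-bin count-vs-time regression.
* **Complex mutations** — clustered events (≥2 mutations within 10 bp in
  one isolate, transitive chaining), compared against SBS-proportional
  expectations; complex-SBS spectra screened against signature
  catalogues by cosine similarity.
* **CPD damage maps** — both-position assignment of strand-aware lesion
  counts, per-bin damage vs dipyrimidine percentages, repair fractions,
  1-kb window scans, and a fold-enrichment score that exposes
  collapsed-repeat coverage artifacts (such as the ~150-copy rDNA locus
  mapped onto its 2 reference copies), with region masking to remove
  them.
* **Synthetic data** — generators for genomes, timing maps, call sets
  with a log-linear timing effect exp(β·time), seeded complex events and
  CPD profiles with a known collapse factor, so every stage is testable
  against ground truth.

See `docs/methods.md` for the conventions and model details.

## Worked example

```python
import dataclasses
import reptimemut as rm

cfg = rm.SimConfig(seed=42, repeat_region=None)       # ~12,000 mutations
genome = rm.gen_genome(cfg)
tmap = rm.gen_timing_map(cfg, genome)
bins = rm.compute_bins(tmap)
beta = rm.beta_for_contrast(-0.08, tmap, bins)        # 8% early excess
records, _ = rm.gen_mutations(dataclasses.replace(cfg, timing_effect=beta),
                              genome, tmap)
res = rm.run_mutation_analysis(genome, tmap, records, bins=bins)["unmasked"]
print(res.bin_table.to_frame().round(1))
print(f"chi-square p={res.chisq.p_value:.3g}, "
      f"nine-bin r={res.regression.estimates['r']:.2f}")
```

prints

```
        observed  expected  observed_pct  expected_pct
early     4090.0    3939.4          34.6          33.4
middle    3981.0    3946.9          33.7          33.4
late      3734.0    3918.7          31.6          33.2
chi-square p=0.000624, nine-bin r=-0.89
```

Observed counts tilt toward early-replicating DNA (34.6% vs 31.6%) while
the composition-based expectations are nearly flat — the chi-square
p-value says the tilt is not explained by sequence context, and the
negative nine-bin correlation says mutation load falls with later
replication time. The scripts in `examples/` walk through each
capability the same way (complex events and signature screening, CPD
maps and the collapse artifact, file round-trips and the per-chromosome
Wilcoxon test).

A thin CLI mirrors the analyses:

```
reptime-mut simulate --seed 1 --contrast 0.36 --out data/
reptime-mut spectrum --genome data/genome.fa --map data/timing.tsv \
    --mutations data/mutations.bed --out results/
reptime-mut cpd --genome data/genome.fa --map data/timing.tsv \
    --lesions data/cpd_0h_plus.wig --lesions data/cpd_0h_minus.wig \
    --rdna --out results/cpd/
```

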