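# plasmacna

Copy-number analysis of circulating tumor DNA (ctDNA) from shallow
whole-genome plasma sequencing, built for liquid-biopsy studies of treatment
resistance — specifically the setting of advanced *EGFR*-mutant lung
adenocarcinoma progressing on osimertinib, where focal amplifications of
bypass-pathway genes (*EGFR*, *ERBB2*, *MET*, *CDK4/6*, *MDM2*, *AKT2*,
*PIK3CA*) and deletions of *CDKN2A*/*RB1* are candidate resistance drivers.

The package covers the whole desk-side pipeline:

* **Read-count profiling** — reads counted in non-overlapping 50 kb windows,
  normalized by total read count, GC-corrected with a robust LOESS, and
  normalized against a healthy-control panel to remove position effects; the
  log2 ratios are segmented by an exact penalized least-squares change-point
  search.
* **Focal SCNA calling** — a segment is a focal amplification iff it is
  < 20 Mb, has mean log2 > 0.2, contains 1–100 genes, stands 0.2 (if it
  contains a known driver gene) or 0.58 (about one extra copy; otherwise)
  above the length-weighted mean log2 of its 20 Mb flanks, has ≤ 50%
  segmental-duplication coverage, and matches no known copy-number
  polymorphism. Deletions mirror the rules below −0.2 and additionally
  require a gene recurrently affected by deletions.
* **Tumor fraction (TF)** — a 7-state hidden-Markov grid search over TF on
  1 Mb bins, with emission means `log2((tf·c + (1−tf)·2)/2)` for copy number
  `c`; samples under the 3% detection threshold are censored as `<3.0%`.
* **Patient annotation** — ddPCR mutation positivity (> 1 copy/mL),
  resistance-related SCNA (rrSCNA) classification against a direction-aware
  gene list, and the evaluability gate (pre-treatment TF < 5% with no SCNAs
  at all ⇒ excluded from outcome analyses).
* **Cohort statistics** — chi-square/Fisher association tests, Mann–Whitney
  and Spearman rank statistics with an explicit policy for censored TF
  values, Kaplan–Meier/log-rank, and Cox proportional hazards with stepwise
  backward elimination.
* **Synthetic data** — a forward simulator for genomes, binned plasma
  counts with GC bias and (optionally overdispersed) counting noise,
  healthy-control panels, and full cohorts with linked ddPCR, response and
  survival outcomes, so every stage is testable without sequencing data.

A 43-patient osimertinib-resistance cohort (paired pre/post plasma samples
with EGFR mutation status, rrSCNA calls, tumor fractions and ddPCR copies)
ships with the package as `plasmacna.datasets`.

## Worked example

```python
import plasmacna as pc

genome = pc.make_genome(n_chrom=2, chrom_length=60_000_000, seed=1)
panel  = pc.simulate_control_panel(genome, 10, pc.SimulationConfig(seed=3))

event  = pc.SimulatedEvent("chr1", 10_000_000, 12_000_000, total_copies=4)
counts = pc.simulate_counts(genome, [event],
                            pc.SimulationConfig(tumor_fraction=0.2, seed=7))

profile  = pc.normalize_against_panel(counts, panel, genome)
segments = pc.segment_profile(profile)
for s in segments:
    print(s.chrom, s.start, s.end, s.n_bins, round(s.mean_log2, 3))
```

prints

```
chr1 0 10000000 194 -0.004
chr1 10000000 12000000 38 0.262
chr1 12000000 60000000 943 -0.003
chr2 1200000 60000000 1156 -0.005
```

The 2 Mb segment at +0.262 is the spiked gain: 4 copies at 20% tumor
fraction gives a mixture of 2.4 copies, `log2(2.4/2) = 0.263`. Longer
narrative scripts — focal calling, tumor-fraction estimation, the cohort
tables, survival analysis — live in `examples/`; each prints its results
with a line on what they mean. A thin CLI mirrors the stages
(`plasmacna simulate|profile|call-focal|estimate-tf|cohort-summary|cohort-stats`).

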