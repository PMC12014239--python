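# dinoretro

Retrogene discovery and characterization in dinoflagellate transcriptomes.

Dinoflagellate nuclear mRNAs all begin with a short spliced leader, the
22-nt **DinoSL** (`DCCGTAGCCATTTTGGCTCAAG`, D = A/G/T), added by spliced-leader
trans-splicing. When a leader-bearing mRNA is reverse-transcribed, reinserted
into the genome and expressed again, the new transcript is trans-spliced once
more and the old leader survives as a 15-nt relic, the **DinoRL**
(`CCATTTTGGCTCAAG` — the DinoSL minus its first 7 nt), sitting immediately
after the fresh leader. A transcript whose 5' end parses as

```
[DinoSL][DinoRL]{1..n}  (a 37-nt tandem for n = 1)
```

is therefore a **retrogene** diagnosis that needs no genome sequence, and the
relic count n records rounds of retroposition or leader recycling. This
package implements that diagnostic and the downstream characterization used
to ask whether such retrogenes are functional genes:

- **leader detection** — degenerate-motif Hamming search (default budget of 5
  mismatches over the whole leader), arrangement classification (SL-RL,
  SL-RL-RL, ...), truncated `CTCAAG`-initial leaders, and position-frequency
  matrices for logo output;
- **transcript processing** — 200-nt length filter, greedy longest-first
  redundancy collapse at 90% identity (identity = aligned matches / shorter
  sequence, free end gaps), longest-ORF extraction on the forward strand;
- **codon usage** — RSCU, GC, GC3s, Wright's effective number of codons
  Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ (range 20–61) and the null curve
  Nc\* = 2 + s + 29/(s² + (1−s)²) for s = GC3s;
- **enrichment** — per-term one-sided hypergeometric (Fisher) tests of the
  retrogene set against its transcriptome, Benjamini–Hochberg correction,
  raw p < 0.01 threshold, gene-overlap redundancy pruning (Jaccard > 0.6)
  and rich factors;
- **expression** — TPM normalization (length-corrected rates rescaled to
  10⁶), TPM > 1 retention, two-sided Wilcoxon rank-sum comparison of
  retrogene vs normal-gene expression, and shared-enrichment correlation;
- **synthetic data** — a fully labelled transcriptome generator (leader
  structure, ~62% coding GC with ~75% GC3s, 5'-truncation, near-identical
  isoforms, negative-binomial counts, a planted enriched term) so every
  stage is testable without downloads.

## Worked example

```python
from dinoretro import (SimParams, generate_transcriptome, scan_5prime,
                       classify_arrangements)

res = generate_transcriptome(SimParams(n_normal=400, n_retro=100, seed=7))
arrangements = [a for t in res.transcripts if (a := scan_5prime(t, budget=5))]
print(classify_arrangements(arrangements).counts)
```

prints

```
{'SL-RL': 83, 'SL-RL-RL': 2}
```

— 85 of the 100 planted retrogenes are recovered (the misses carry the
truncated `CTCAAG` leader form or lost their 5' end to assembly noise; with
zero-noise parameters recall and precision are both 1.0), 83 with a single
relic and 2 with a double relic. Longer narrative scripts, one per
capability, live in `examples/`; each prints the numbers it computes and a
line on what they mean. A thin CLI mirrors the stages
(`dinoretro simulate|detect|collapse|orf|codon|enrich|express|report`).

The enrichment stage on the generator's default conditions (300 retrogenes
among 3000 genes, planted term carried by 50% of retrogenes vs 5%
background) reports, for the planted term:

```
term_id   k   n  odds_ratio            p        p_adj  rich_factor
  T_ENR 159 295   19.805821 1.730209e-95 7.093858e-94     0.538983
```

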