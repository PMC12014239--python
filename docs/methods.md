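# Methods

## The retrogene diagnostic

Spliced-leader trans-splicing puts the 22-nt DinoSL
(`DCCGTAGCCATTTTGGCTCAAG`, D = A/G/T) at the 5' end of every dinoflagellate
nuclear mRNA. Retroposition of a leader-bearing mRNA followed by renewed
expression and re-trans-splicing leaves the 15-nt relic DinoRL
(`CCATTTTGGCTCAAG`) — the old leader minus the 7 nt displaced by the new
splice — immediately downstream of the fresh leader. The detector therefore
parses transcript 5' ends against the grammar `SL RL{1..n}` and calls a
retrogene whenever at least one relic follows an accepted leader. Because
the relic is literally the leader's 3' suffix, every full leader contains
the relic *string* at offset 7; only relics extending *past* the leader end
are evidence of retroposition, and the parser's anchored, non-overlapping
consumption enforces that.

### Matching model

Motifs are IUPAC-degenerate and matched by Hamming distance; an ambiguous
base in the transcript always counts as a mismatch. The default budget is 5
mismatches shared across the whole leader (the behaviour of a single
37-mer pattern search at 5 mismatches); `budget_scope="per-motif"` budgets
each unit independently instead. Leader placements are tried at offsets
0..`max_offset` (default 0 — the signature is anchored at the 5' end; up to
~10 tolerates spurious assembled bases). Placements are ranked by
(mismatches, start, full-before-truncated), relics are consumed greedily
left-to-right with no gaps — relic units are fixed-length and contiguous by
the splicing mechanism, so greedy consumption *is* the exhaustive
segmentation — and the best-ranked placement yielding ≥ 1 relic is
returned. Transcripts whose leader begins with the truncated form `CTCAAG`
are parsed only when `allow_truncated` is set and are reported as their own
`SLt-*` classes rather than merged into the SL classes: the canonical
selection rule requires a full DinoSL, while the truncated form is a
consensus-level observation. All coordinates are 0-based, half-open.

## Transcript processing

- **Length filter**: transcripts shorter than 200 nt are removed (≥ is
  kept).
- **Redundancy collapse**: greedy longest-first clustering, processing by
  (length desc, id asc); a transcript joins the first cluster whose
  representative aligns at identity ≥ 0.90, else founds a cluster, so the
  longest isoform always represents. Identity is computed from a global
  alignment with free end gaps (match 1, mismatch 0, internal gaps
  penalized at 1 + 2⁻²⁰) as matched positions / length of the shorter
  sequence — a fragment identical to part of its parent scores 1.0. The
  2⁻²⁰ excess over 1 makes the optimal score decode to a unique
  (matches, gaps) pair for sequences under 2²⁰ nt, so the match count is
  read off the score without a traceback. An exact-word prescreen
  (pigeonhole bound: at identity t a shorter sequence of length L keeps at
  least L(1 − w(1−t)) − w + 1 of its w-mers intact; half that count is
  demanded, word size w = 8 by default) avoids most alignments. The
  clusterer is deliberately quadratic and meant for retrogene-set collapse
  (10³–10⁴ sequences), not whole-assembly clustering.
- **ORF extraction**: frames 0–2 of the forward strand only — the leader
  fixes orientation. Candidates run from an ATG (or from the frame start
  when `require_start=False`, flagged `partial5`; segments after an internal
  stop always need an ATG) to the next in-frame stop or the sequence end.
  The longest candidate of ≥ `min_aa` (default 100) residues wins, ties to
  the smaller start; `end` includes the terminal stop, the peptide does
  not. Standard nuclear genetic code throughout.

## Codon usage

Codons are counted in frame 0; trailing partial codons and codons
containing N are skipped; stop codons are counted but excluded from
synonymous statistics. RSCU is family size × count / family total (Ser,
Leu, Arg are single 6-fold families; Met and Trp report RSCU 1 when
present). GC3s is the G+C fraction at third positions of synonymously
variable codons (Met, Trp, stops excluded). Nc follows Wright: per family
with n ≥ 2 counted codons, F̂ = (nΣp̂² − 1)/(n − 1); per degeneracy class,
F̄ averages the families with F̂ > 0; Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,
clipped to [20, 61]. A missing 3-fold class (Ile is its only member) is
imputed as (F̄₂ + F̄₄)/2; any other missing class has its weight
redistributed proportionally over the estimable classes (the 2 + Σ m/F̄
partial sum is rescaled by 18/Σm so the statistic stays on the 20–61
scale); Nc is undefined with fewer than two estimable classes. The
random-usage expectation is Nc\*(s) = 2 + s + 29/(s² + (1−s)²).

## Enrichment

Every term carried by at least one foreground (retrogene) gene is tested
one-sided for over-representation: p = P(X ≥ k), X ~ Hypergeom(N, n, K),
with the odds ratio from the 2×2 table (infinite when an off-diagonal cell
is 0). The background is all annotated genes of the same transcriptome,
retrogenes included. BH-adjusted p-values are always reported, but the
retention threshold defaults to raw p < 0.01, matching the published rule;
`use_adjusted=True` switches the gate to adjusted p. Redundancy pruning
processes retained terms by ascending p (term id as tie-break) and drops a
term whose foreground gene set has Jaccard overlap > 0.6 with an already
retained term. This is a gene-overlap stand-in for ontology-graph semantic
simplification: the intent — drop near-duplicate terms — is preserved
without an ontology dependency, but terms related only through the GO graph
(not through shared genes) are not merged. For the retrogene vs
high-expression comparison the pruning cutoff is 0.7. The rich factor is
k/n: foreground genes with the term over background genes with the term.

## Expression

TPM: rateᵍ = countᵍ/(lengthᵍ/1000), tpmᵍ = 10⁶·rateᵍ/Σrate. Lengths are
full transcript lengths (inputs are expected counts, not fragment counts,
so no effective-length correction). Retention is strict: tpm > 1. The
class comparison is a two-sided Wilcoxon rank-sum with mid-ranks for ties;
with both samples ≤ 8 observations the null is enumerated exactly over all
rank assignments, otherwise a normal approximation with tie and continuity
corrections is used. The discreteness of the exact null means the normal
approximation can differ from enumeration by up to ~0.09 at 2-vs-2 and
~0.03 at 4-vs-4; the switch at 8 keeps the approximation's error below a
percent where it is actually used. Shared-enrichment comparison reports
the shared-term fraction relative to the smaller pruned table and the
Pearson correlation of −log₁₀ adjusted p over shared terms (undefined
below 3 shared terms).

## Synthetic transcriptomes

The generator emits what the analysis consumes: FASTA transcripts, a truth
table, an annotation table and a count table, all reproducible
byte-for-byte from one integer seed (a single `numpy` generator drives
every draw).

Structure per transcript: leader, then `ATG` + coding body + stop. The
leader is the full DinoSL with D drawn uniformly from {A,G,T}, or with
probability `p_trunc_leader` (default 0.3) the truncated `CTCAAG` form;
retrogenes append 1–4 DinoRL copies with weights {1: 0.95, 2: 0.04,
3: 0.008, 4: 0.002}, making ~95% of retrogenes single-relic. Defaults are
300 retrogenes among 3000 transcripts of 150–2400 nt (the lower bound sits
below the 200-nt filter on purpose).

Coding sequence: a random peptide back-translated by the third-codon
sampler, which picks synonymous codons so the third position is G/C with
probability `gc3_target` (default 0.75), renormalized within each family.
Controlling GC3 independently of amino-acid composition leaves overall GC
free, so amino acids are drawn from an exponentially tilted distribution
whose tilt is set by bisection to hit `gc_target` (default 0.62) in
expectation. Realized compositions land within a point or two of both
targets.

Noise: leader point substitutions at `leader_mut_rate` (default 0.01,
positions recorded in the truth); 5'-truncation with probability 0.05
removing 1–30 nt (the truth records leader_start = −k for k clipped
bases); with probability `dup_rate` (default 0.1) a transcript is re-emitted
as a 3'-truncated isoform (80–95% of its length) with substitutions at
1 − `dup_identity` (default 0.95) applied downstream of the leader — one
locus shares one leader, and the leader truth stays well-defined.

Annotations: 1–3 terms per gene from a 40-term vocabulary, plus one
planted term carried by retrogenes with probability 0.5 vs 0.05 background.
Counts: negative-binomial, dispersion 5, mean 100 for normal genes and 200
for retrogenes — a designed 2× effect for power checks.

What the generator does **not** emulate: read-level error, coverage-driven
assembly artifacts beyond 5' loss, homologous gene families, UTRs,
composition heterogeneity along a transcript, or any mechanistic model of
why 5' ends are lost. Passing tests therefore demonstrate correctness of
the algorithms under controlled conditions, not robustness to every
property of real assemblies.

## Problem sizes

The test suite runs simulations of 300–3000 transcripts; the acceptance
script uses a 200-transcript oracle battery, a 500-transcript zero-noise
recovery run, 20 seeds of the 3000-transcript enrichment condition and 50
seeds of the 600-transcript expression condition, completing in about 90 s
on one CPU. These sizes were chosen as the smallest at which the binomial
error bars on the checked fractions are informative.

## Known limitations

- The collapse stage is a greedy quadratic clusterer, not a CD-HIT
  replacement; whole-assembly inputs (10⁵ transcripts) are out of scope.
- Enrichment pruning cannot merge terms related only through the ontology
  graph.
- The ORF finder reports a single best forward-strand ORF; it does not
  score coding potential.
- Leader detection is pattern-based; a position-weight-matrix scorer and
  splice-acceptor prediction are deliberately not included.
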