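# Methods

## The estimator

Input is the all-alignments output of a Bowtie-v1-style aligner (one
tab-separated line per alignment; only read name, strand, reference and
0-based offset are consumed) plus a gene-size file naming every gene
model and its length in bp. Reads are grouped by exact read-name string;
paired-end mates are treated as independent reads. A read whose candidate
locations all lie on one gene is *unique* for counting purposes even if
it hits that gene at several positions; all other reads are ambiguous.

Each bootstrap iteration assigns every ambiguous read uniformly at random
to one of its alignment **records** — a gene hit at two positions by one
read gets weight 2/|locations| — and the resulting per-gene counts are
converted to RPKM with the fixed denominator N = number of aligned reads
(reads with ≥ 1 alignment). N is identical in every iteration and in the
unique-read column, so all reported columns are on one comparable scale;
unaligned reads never enter the program. Per-gene mean and SD over
iterations use the sample (n−1) denominator, treating the iterations as a
sample from the assignment distribution; aggregation uses streaming
Welford moments so memory is O(genes), not O(genes × iterations).

The significance of detected expression models a gene's expression as
N(μ, σ²) with the bootstrap moments and reports p = P(X ≤ 0) = Φ(−μ/σ):
small p means the expression distribution is bounded away from zero.
Degenerate rules precede the formula: μ = 0 → p = 1 (the gene never
received a read) and σ = 0 with μ > 0 → p = 0 (identical counts in every
iteration, e.g. only unique reads). The zero tests are exact
floating-point equalities on purpose — Welford aggregation yields an
exactly zero mean for a never-hit gene and exactly zero M2 for a
constant-count gene, so no tolerance is needed or wanted. Raw p-values
are Benjamini–Hochberg adjusted (statsmodels' step-up implementation)
over all gene models, and a gene is called expressed when the adjusted
p is strictly below α = 0.05 by default.

Baselines: *random assignment* is a single draw of the same re-allocation
(denominator N), equivalent in distribution to one bootstrap iteration;
*unique-only* counts reads with exactly one alignment record and uses its
own denominator (the number of uniquely aligning reads), because it
models a separate aligner run that discards ambiguous reads outright.
With no significance measure, baselines call expression as RPKM > 0.

## Determinism and parallelism

Every iteration's random stream derives from (seed, iteration index) via
numpy `SeedSequence`, and iterations are aggregated in fixed 32-iteration
chunks whose moments are merged in chunk-index order (the standard
pairwise mean/M2 combination). Worker threads only parallelize chunk
computation, so the output is bit-identical for any worker count — a
contract the tests assert for 1, 2 and 4 workers.

## Synthetic validation harness

The simulator emulates a metatranscriptome whose difficulty comes from
families of near-identical gene models. Defaults (the harness's standard
study conditions): 2000 genes with lengths uniform on 500–2500 bp
(typical transcript lengths), 10 duplicate families of size 2 generated
by copying a seed sequence and substituting each position independently
with probability 1 − identity (identity 0.98, substitutions always to a
different base so the parameter is the expected identity), 50 % of genes
expressed. Expression weights are i.i.d. log-normal (μ_log = 0,
σ_log = 1.5, ≈ 3 orders of magnitude dynamic range, typical of bulk
RNA-seq); the log-normal is a declared stand-in for a real expression
profile. Exactly round(frac × n) genes are expressed.

Reads are error-free forward-strand 46-mers: a gene is chosen with
probability ∝ weight × (length − 46 + 1) — weights act as transcript
molarity, so longer transcripts yield proportionally more reads — and the
start is uniform over valid positions. The published `true_rpkm` is the
RPKM of the *expected* origin count, a target independent of sampling
noise; realized origin counts are kept for diagnostics. The internal
aligner reports every exact occurrence of each read across all gene
sequences (a hash of the distinct read sequences scanned over every gene
k-mer window), so error-free reads always recover their origin. Real
data should be aligned with Bowtie reporting all alignments instead.

What the simulator does **not** model: sequencing errors and quality
variation, reverse-strand sampling, intron/exon structure, paired ends,
and fragment-level biases. Passing validation therefore demonstrates the
re-allocation logic and its calibration under ambiguity, not robustness
to alignment mismatches or library artifacts.

Validation problem sizes were chosen to mirror the average read depth of
full-scale experiments at desk scale: 300 000 reads over 2000 genes
(~150 reads/gene) stands in for a 10 M-read run over a ~68 000-model
transcriptome, and 30 000 reads (~15 reads/gene) for a 0.5 M-read run.
With 100 bootstrap iterations, median presence/absence accuracy of
BH-corrected calls exceeds 99 % at the deeper setting and the median
Spearman correlation with the known expression is ≈ 0.97 at the shallow
one (three replicate seeds each; `scripts/acceptance.py` recomputes
both). The unique-only baseline's false positives are exactly zero on
error-free reads — a unique exact match can only be the origin gene —
while its rank correlation suffers on family genes.

## Evaluation conventions

Truth-positive means expression weight > 0. Accuracy is (TP + TN) / all
genes. False-positive % is 100 × called-but-unexpressed / called (0 when
nothing is called); the share-of-truth-negatives variant is exposed
separately as `false_positive_pct_of_negatives`. Spearman correlation is
computed over **all** genes with mid-ranks for ties (the many zero–zero
ties included), via scipy. MA coordinates are M = log2(calc/known),
A = log2((calc + known)/2) for genes with both values positive; pairs
with a zero are dropped and counted, since the log is undefined there.

## Numerical and design notes

- Bootstrap iterations default to 100: the moments of the assignment
  distribution are low-dimensional per gene and stabilize quickly; the
  iteration count is user-settable where tighter SDs are needed.
- Unknown reference names in the alignment file are a hard error, not a
  warning — a silent index/gene-table mismatch would corrupt the RPKM
  denominator invisibly.
- The unique-RPKM column shares the full denominator N for cross-column
  comparability; the unique-only *baseline* deliberately does not (it
  models a different experiment).
- `iterations ≥ 2` is enforced (sample SD undefined below that).
- With zero aligned reads every estimate is zero and the μ = 0 rule
  forces all p-values to 1.
- Known limitations: no splice-variant discovery (ambiguity is resolved
  only at the gene-model level); the normal model for the bootstrap
  distribution is an approximation that is conservative for genes whose
  count distribution is strongly skewed at very low depth.
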