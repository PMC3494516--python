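# bowstrap

Bootstrap estimation of gene-model expression from short-read RNA-seq
alignments, with a statistical significance for presence/absence of
detected expression.

## The problem

A sizeable fraction of RNA-seq reads — often around a third in
transcriptomes with duplicated or cross-species homologous gene models —
cannot be aligned to a unique location. Discarding these ambiguous reads
under-reports expression of high-identity gene families; committing each
one to a single arbitrary location over-reports it and gives no sense of
the uncertainty introduced.

`bowstrap` treats the ambiguity itself as the noise source. Expression is
measured in RPKM (reads per kilobase of gene sequence per million aligned
reads),

    RPKM_g = count_g / (L_g / 1000) / (N / 10^6),

with `L_g` the gene-model length in bp and `N` the total number of aligned
reads. In each bootstrap iteration, every multiply-aligning read is
assigned uniformly at random to one of its candidate alignment locations,
yielding one complete RPKM vector; across iterations each gene gets a mean
μ and standard deviation σ. Significance of detected expression is the
cumulative-normal (CND) p-value

    p = Φ(−μ/σ),

the probability that a normal variate with the bootstrap moments is ≤ 0
(with μ = 0 ⇒ p = 1 and σ = 0, μ > 0 ⇒ p = 0), Benjamini–Hochberg
adjusted across all gene models. Uniquely aligning reads are reported per
gene as well — they are a hard lower bound on every iteration's count and
help separate members of homologous families.

The package also implements the two standard non-bootstrap comparisons
(single random assignment of ambiguous reads; unique-reads-only), a
synthetic-transcriptome read simulator with known expression truth and a
built-in exact-match aligner, and evaluation metrics (accuracy,
false-positive %, Spearman rank correlation, MA values).

## Worked example

Simulate a 60-gene transcriptome containing three duplicate-gene families
(98 % within-family identity), half the genes expressed, 5000 error-free
46-mer reads; then estimate expression three ways and score against the
known truth:

```sh
bowstrap simulate toy --n-genes 60 --length-min 300 --length-max 600 \
    --n-families 3 --n-reads 5000 --seed 9
bowstrap run toy.genes.tsv toy.bowtie.txt bowstrap.tsv --iterations 100 --seed 1
bowstrap run toy.genes.tsv toy.bowtie.txt random.tsv --method random --seed 1
bowstrap run toy.genes.tsv toy.bowtie.txt unique.tsv --method unique
bowstrap evaluate toy.truth.tsv --bowstrap bowstrap.tsv \
    --random random.tsv --unique unique.tsv
```

The expression table starts:

```
gene	length_bp	unique_reads	unique_rpkm	mean_rpkm	sd_rpkm	cnd_pvalue	bh_pvalue
gene00000	408	528	258824	328333	4097.13	0	0
gene00001	408	0	0	70686.3	4097.13	5.34577e-67	1.06915e-66
gene00002	365	0	0	11611	1753.1	1.75891e-11	3.29795e-11
```

`gene00000` and `gene00001` are a duplicate pair: the first is truly
expressed (528 reads align to it uniquely, in its diverged positions), the
second receives only the ambiguous reads shared with its twin. The
bootstrap reports both with tight confidence bands; the unique-read column
is what tells them apart. `evaluate` prints:

```
  method  accuracy  false_positive_pct  spearman  n_called
bowstrap    0.9500              9.0909    0.9250        33
  random    0.9500              9.0909    0.9280        33
  unique    1.0000              0.0000    0.9978        30
```

At this deliberately tiny scale, 10 % of genes sit in duplicate families,
so unexpressed family partners soaking up shared reads dominate the
false-positive column; on realistically proportioned transcriptomes
(see `scripts/acceptance.py`) the bootstrap's accuracy exceeds 99 % with
well under 1 % false positives, while the unique-only baseline never
produces a false positive on error-free reads but misses family genes.

On real data, replace the `simulate` step with an actual Bowtie run that
reports **all** alignments (`bowtie --all <index> <reads.fq> <out.txt>`)
and supply the matching gene-size file (`name<TAB>length_bp`).

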