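# Methods

This note documents the models, conventions and parameter choices behind
`luctrap`, and what the synthetic-data validation does and does not show.

## Junction model and coordinate conventions

A T-DNA junction read is modelled as the read-strand layout
`revcomp(LUC head) + revcomp(barcode) + revcomp(border) + genomic flank`,
where the vector context is `border (28 nt) + barcode (12 nt) + LUC 5′
fraction` and the genomic flank abuts the right-border (RB) end of the
insert. Extraction scans both read orientations for the border anchor with
at most `max_template_mismatch` substitutions (default 2). A read with two
or more anchor occurrences is discarded as ambiguous rather than guessed
at; a read whose barcode slot or flank is incomplete is discarded as
truncated.

Coordinates are 0-based half-open in memory; GFF3 on disk is 1-based
inclusive, and all conversions happen in the I/O layer only. The
**RB-junction coordinate** of an insertion is the reference position of
the genomic base immediately adjacent to the border (the first flank base
of the read), and the insert strand is the strand on which the LUC CDS
reads 5′→3′. A flank matching the reference forward strand therefore
implies a `-` insert with the junction at the left end of the aligned
interval; a reverse-complement match implies `+` with the junction at the
right end. Reverse-complementing a flank consequently flips the reported
strand and maps to the same aligned interval — the same physical junction,
with the coordinate at the interval's other end. No convention can keep
the single-base coordinate itself invariant under reverse complementation,
because border adjacency moves to the opposite end of the flank.

## Flank mapping

Mapping is substitution-only (no indels), mirroring `bowtie -v`-style
semantics: all genome locations within Hamming distance
`max_mismatches = 3` over the full flank, on either strand, are
enumerated. The search seeds with non-overlapping k-mers (`k = 10`) and
verifies candidates against the genome with a vectorised Hamming count; by
the pigeonhole principle this is exhaustive whenever
`flank ≥ (max_mismatches + 1) · k`. Shorter flanks (≥ `min_flank_len = 20`)
fall back to a full scan so completeness is never lost. Ties at the best
distance are never broken: two or more best-scoring locations yield
`multi_mapped` and no alignment, because pair calling requires a unique
locus. Flanks with more than `max_n = 2` non-ACGT characters are dropped
as low quality. The `min_flank_len` default of 20 nt is this package's
choice; with ≤ 3 mismatches a 20-mer is still effectively unique in a
genome of the sizes considered here.

## Pair calling

Junction evidence is aggregated per exact barcode string (no barcode
error-correction or clustering). Candidate loci on the same chromosome and
strand whose positions differ by at most `merge_window = 5` bp are
collapsed — summing counts, keeping the modal position (ties to the
smallest) — to absorb junction-trimming jitter. Calling then applies three
criteria per barcode: a candidate locus needs `min_reads = 2` supporting
reads; the single candidate must carry `min_dominance = 60 %` of **all**
reads bearing the barcode (the denominator deliberately includes unmapped
and artefact reads); and two or more candidates exclude the barcode
(`multi_insert`) outright, even if one of them passes the dominance bar.
The secondary-locus threshold is `min_reads`, so a lone stray read cannot
veto an otherwise clean call; treating *any* second locus as a veto is one
configuration change. Barcodes whose reads never map anywhere are
`unmapped`; a sub-threshold or sub-dominant single candidate is
`low_support` / `low_dominance`.

## Quantification

`level = (rna/rna_total) / (dna/dna_total) × scale` with `scale = 10,000`.
Barcodes with ≤ 5 DNA reads are omitted (unreliable denominator); RNA
counts ≤ 5 are zeroed before normalisation (background). Library totals
are the number of reads with an extractable barcode, taken **before**
either threshold: the thresholds are described as per-barcode filters, so
they do not redefine the library size. A line is "transcribed" iff its
level is > 0 after these rules.

## Classification

Insertion type uses the full annotated gene span (introns and UTRs
included) of protein-coding genes only, tested at the single RB-junction
base: overlap with a same-strand gene is `genic_sense`, opposite-strand
only is `genic_as`, no overlap is `intergenic`. WT-overlap types i–iv
cross reporter transcription (level > 0) with WT transcription (junction
base inside ≥ 1 WT transcribed region). The WT-region test is
strand-agnostic by default — the i–iv dichotomy concerns transcriptional
territory, not orientation — with `strand_aware=True` available for the
stricter reading. FPKM of multiple overlapping WT isoforms is summed.

## Summary statistics

* Percentile bins (High 100–67, Mid 66–34, Low 33–1) are computed among
  transcribed lines only, from maximum-rank percentiles, so ties share the
  higher bin and n distinct levels split 3-ways within ±1.
* Decade histogram bins are `floor(log10 level)` clamped to [1, 7], with
  untranscribed/omitted lines in `ND`; per-type fractions normalise each
  insertion type to 100 %.
* The lower/higher split puts decades ≤ 4 in the lower class (10¹–10⁴) and
  ≥ 5 in the higher class, normalised per type over transcribed lines.
* Stratum-normalised activation is `n_iii/(n_iii+n_iv)` (WT-untranscribed)
  and `n_i/(n_i+n_ii)` (WT-transcribed); the ratio is scale-free, so
  printed percentage shares can be used in place of counts.
* Spearman correlation of level vs WT FPKM uses average ranks for ties and
  is flagged undefined for constant vectors.
* Mendelian recovery of a screen of hemizygous T1 lines grown at
  `seeds_per_line` seeds each: `P(recovered) = 1 − wt_fraction^seeds`,
  with `wt_fraction = 1/4`.
* Reported percentages are rounded to one decimal, half away from zero;
  counts recovered from printed shares use nearest-integer of share × n.
  Rounded three-way shares can sum to 100.0 ± 0.1.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Genome**: 5 chromosomes × 120 kb by default, random uniform base
  composition, non-overlapping genes laid down with jittered lengths and
  gaps to cover 50 % of the sequence (the genic/intergenic split of the
  *A. thaliana* genome is approximately even). Scaled-down sizes keep
  exhaustive oracles and full pipelines fast while leaving k-mer mapping
  statistically comfortable (a 40–54-nt flank is effectively unique).
* **WT transcriptome**: 70.4 % of genes transcribed; intergenic regions
  added so 97.8 % of transcribed regions are genic; FPKM log10-normal
  (mean 1.0, sd 0.6 — typical single-digit-to-hundreds FPKM).
* **Cohort**: uniform insertion placement (with a 200-bp end margin so a
  junction read's flank never runs off a chromosome), random strand,
  activation Bernoulli per insertion type with defaults
  (0.66, 0.27, 0.27) for (genic sense, genic AS, intergenic) — matching
  the screen-level observations that roughly one line in three activates
  overall and genic-sense traps activate most often. Active levels are
  `10^Normal(mean, 1.0)` truncated (clipped) to [10¹, 10⁷], with mean 5
  for genic-sense (promoter trapping) and 4 otherwise (de novo
  activation), reproducing the observed level range and modes.
* **Junction library**: clean reads as in the junction model (110 nt:
  16 nt LUC segment, 12 nt barcode, 28 nt border, 54 nt flank); the three
  restriction-enzyme sub-libraries of the wet protocol are collapsed into
  one, since the junction coordinate the pipeline consumes is
  enzyme-independent. Optional artefacts at configurable per-read/per-line
  rates: barcode base substitutions, chimeric flanks, barcode collisions
  and multi-insert lines. Artefact rates default to 0 and are free
  parameters of the noise model, not estimates.
* **Count libraries**: multinomial read counts, DNA with near-equal
  per-insertion weights (optional log-normal copy-number jitter), RNA with
  weights ∝ DNA weight × true level. Reads are vector amplicons
  (border + barcode + LUC head). Base qualities everywhere are a constant
  placeholder; quality trimming is out of scope.

Everything is deterministic for a fixed seed, byte-identically so for the
written FASTA/GFF3/FASTQ/TSV outputs.

What the generator does **not** emulate: base-call errors outside the
barcode, indels, vector backbone read-through, tandem or truncated T-DNA
structures (such lines were excluded from the real analysis), fragment
length variation, GC or mappability biases, and pericentromeric insertion
bias. Passing end-to-end tests therefore demonstrates correctness of the
decision rules and estimators under the assumed read structure, not
robustness to every artefact of real libraries.

## Validation sizes and statistical design

Exhaustive oracles: the pair-calling rule is checked against an
independent evaluator on **all** support tables with ≤ 4 loci and ≤ 12
total reads (603 tables); the flank mapper against a brute-force
full-genome Hamming scan on 1,000 random flanks (0–4 planted
substitutions, both orientations) over a 100-kb genome.

End-to-end recovery uses an artefact-free 100-line screen (3 × 100 kb
genome, junction depth 10, DNA and RNA depth 10⁶): all lines must be
called at their true locus and computed levels must track true levels at
Spearman ρ ≥ 0.95. Parameter recovery uses 2,000 lines at junction depth
5, DNA depth 2 × 10⁵ and RNA depth 5 × 10⁶, requiring each per-type
transcribed fraction within 3 binomial SDs of its generating probability.
The RNA depth is sized from the detection threshold: because the RNA
multinomial is dominated by high-level lines and RNA counts ≤ 5 are
zeroed, the smallest detectable level is ≈ 5·ΣL/depth; at these settings
that floor sits near 5 × 10², so the expected detection loss for the
log-normal level distribution stays well inside the 3-SD band. This is a
property of the assay design itself: very weakly transcribed lines are
indistinguishable from silent ones at finite RNA depth.

## Known limitations

* Substitution-only alignment: an indel near the junction shifts or kills
  the mapping rather than being absorbed.
* Exact barcode matching: sequencing errors in the barcode create phantom
  singleton barcodes; they dilute dominance denominators but are never
  merged back into their parent line.
* The dominance rule operates per barcode; it cannot rescue a true locus
  whose reads are split across a merge-window-exceeding junction spread.
* Uniform insertion placement ignores the integration biases of real
  T-DNA transformation; cohort composition statistics from synthetic runs
  reflect interval lengths, not biology.
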