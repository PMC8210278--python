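# Methods

This note documents the statistical model behind `lnccensus`, the numerical
choices made where a design was genuinely open, and what the synthetic-data
generator does and does not emulate. Nothing here states an empirical result
that the test-suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model

All intervals are 0-based half-open on a named sequence; GTF rows (1-based
closed) and SNP tables (1-based positions) convert at the parsing boundary
and convert back on write. A single internal convention removes the usual
source of off-by-one errors when BED-style and GTF-style inputs are mixed.
Strand is carried through but ignored by every intersection operation, which
is the default behaviour of the standard interval tools this package
replaces. Two intervals overlap when they share ≥ 1 nt; the half-open
convention makes book-ended intervals non-overlapping.

Annotation biotypes collapse to three classes — `protein_coding`, `lncRNA`,
`other` — via a YAML vocabulary shipped with the package
(`lnccensus/data/biotypes.yaml`) and overridable per call, since annotation
releases differ in which raw `gene_type` strings constitute the long
non-coding set.

## Liftover

A source interval is remapped through the single best-scoring chain that
overlaps it; there is no multi-chain stitching, matching the single-hit
behaviour of the standard liftover tool. Within the chosen chain every base
falling in an aligned block maps by block arithmetic, and the result is the
interval from the minimum to the maximum mapped target position (so target
gaps inside the interval are bridged). Thresholds:

* `min_match` (default 0.1) — minimum fraction of the interval's bases in
  aligned blocks, relative to its full length;
* `min_blocks` (default 0.1) — the same numerator relative to the bases
  falling inside the chain's span. The reference semantics of this knob are
  under-documented; this interpretation was chosen because at 0.1/0.1 the
  `min_match` condition dominates, so the choice is inconsequential at the
  default settings.

An interval whose bases all fall in inter-block gaps is unmapped with
reason `empty_projection`; reverse-strand chains flip target coordinates
back to forward convention. Failures are never errors: each carries a
machine-readable reason so the liftover report can break down losses.

## Gene assignment

Assignment is at gene-span level (minimum transcript start to maximum
transcript end), not exon level, because insertion positions within a
recurrently hit locus are imprecise — an intronic transposon perturbs the
gene as effectively as an exonic one. Protein-coding genes take precedence:
an interval touching both a pc gene and a lncRNA is credited to the pc gene
only, which makes the lncRNA calls conservative. All overlapped genes of
the winning category are reported. `other`-biotype genes (snoRNA, miRNA,
etc.) are transparent — they neither capture an interval nor prevent it
from being called intergenic.

## Enrichment statistics

Every comparison uses a one-sided exact test on a 2×2 table built by
treating each nucleotide as a Bernoulli unit:
`(hits_set, set_nt − hits_set, hits_baseline, baseline_nt − hits_baseline)`.
The tail probability is computed from the exact hypergeometric pmf in log
space (`scipy.special.gammaln` + `logsumexp`), which is numerically stable
at megabase-scale margins; values are clipped into `(0, 1]`. The test-suite
verifies it against full integer enumeration on every table with margins
≤ 30 and against an independent library implementation on random tables.
Degenerate tables (a zero margin) report p = 1 rather than an error when
they arise inside a density comparison, since they carry no evidence of
enrichment. No multiple-testing correction is applied across the handful of
headline comparisons; the per-cancer-type differential-expression FDR is
assumed corrected upstream by the caller that produced the table.

Gene "length" differs by analysis, following what each signal can hit:
insertion sites and CNVs use the merged gene span; SNP density uses the
merged exon body (germline variants are counted in exons only). An
`exonic` length mode is available for the insertion-site density as well.
For set-level density an interval overlapping k set genes counts once; the
per-gene tallies report it once per gene.

The intergenic baseline for insertion-site density is the genome minus the
merged pc+lncRNA spans — deliberately not minus *all* gene spans, so that
the baseline denominator matches the definition of the `intergenic`
assignment category (`other` genes are transparent there too). With the
default annotation densities the difference is a fraction of a percent.

The direction-concordance test considers only differentially expressed
genes (strict thresholds: FDR < 0.05 and |log2FC| > 1, matching the
convention that a value exactly at the cut does not pass). A gene's sign
comes from its most significant passing record. Oncogenes are tested for
excess positive signs, tumour suppressors for excess negative signs,
against the expression-matched controls; genes labelled `both` must be
excluded by the caller, and an empty class is reported as skipped rather
than tested.

## Permutation null

`shuffle_null_overlap` re-places each query interval uniformly over all
valid start positions (chromosome drawn proportionally to its number of
valid starts; lengths preserved exactly; shuffled intervals may overlap
each other, and no exclusion regions are applied unless supplied). The
statistic is the number of query intervals with ≥ 1 target hit; the number
of distinct targets hit is reported alongside, since both tallies are of
interest when targets are transcripts. The empirical p-value uses the
add-one estimator `(1 + #{null ≥ observed}) / (N + 1)`, which is never
zero and is uniformly distributed under the null up to discreteness of the
overlap count. The acceptance suite verifies calibration on 200 null
datasets (80 queries of 200 nt vs 80 targets of 500 nt on a 2 × 100 kb
genome, 1000 iterations each): the fraction of p ≤ 0.05 must land in
[0.02, 0.10] — the test is conservative, never anti-conservative, because
the statistic is integer-valued.

## Expression matching

Controls are matched on `log10(FPKM + 0.01)` binned into 20 equal-width
bins over the pooled target+candidate range. The pseudocount keeps
zero-expression genes in a dedicated lowest bin; both knobs are arguments.
From each bin the sampler draws `λ · t_b` candidates without replacement,
where `t_b` is the target's bin count and `λ = min_b(c_b / t_b)` over bins
containing both targets and candidates — one global factor, so no bin is
overdrawn and the target's distribution shape is preserved. Target bins
with no candidates at all are skipped and recorded in the diagnostics.
This binned matcher is a declared reimplementation of the idea behind the
commonly used matching scripts, not a clone of any particular one. The
achieved two-sample KS distance (and the unmatched pool's, for reference)
is part of the result.

## Census integration

Evidence records from literature curation, mutagenesis orthology and
CRISPRi screens are unioned over genes that are lncRNAs in the supplied
annotation; anything else is dropped into the report with a reason.
Functional labels resolve commutatively: any og+ts combination (or an
explicit `both`) gives `both`; one direction gives itself; mutagenesis-only
genes stay `unknown` because an insertion site implicates a gene without
revealing the direction of its effect. When literature and CRISPRi disagree
on direction the entry is labelled `both` — no source outranks another.
Novelty is counted in the declared source order (literature → mutagenesis
→ crispri, configurable): a gene is novel to the first source listing it,
which guarantees novel counts sum to the union size (asserted on every
run). Evidence-level strings are preserved verbatim; cancer-type terms are
accumulated as a sorted union.

## The synthetic-data generator

The generator emulates the full input universe of the analysis at a scale
that keeps the complete pipeline under a minute: two target chromosomes of
1 Mb (and source chromosomes slightly larger), about a 1,300-fold linear
reduction of a mammalian genome. Element counts and sizes are scaled to
preserve the *statistics* rather than the literal numbers: the defaults
place 50 protein-coding genes (2–5 kb), 400 lncRNAs (0.8–1.6 kb), 10
`other` genes, 4,000 insertion sites, 2,000 cancer-trait SNPs (plus 300
non-cancer rows that exercise the trait filter), 300 CNVs and 150
unannotated transcripts. These densities are far higher per nt than real
data; they are chosen for statistical power of the recovery tests, and the
per-nt *ratios* (the planted folds) are what the pipeline is asked to
recover.

Key modelling choices:

* **Chain geometry.** Blocks of 5–20 kb tile the target chromosome with
  small target-side gaps (≤ 200 nt) and source-side gaps sized so blocks
  cover ~85% of the source. Unmappable mass therefore sits almost entirely
  on the source side: ~15% of insertion sites fail liftover (mostly
  `empty_projection`), while target-side coverage stays near 100% so the
  intergenic baseline is not diluted by unliftable target sequence.
* **Insertion sites** are planted on the *source* genome by a two-rate
  process: per-nt weight `cis_enrichment_fold` (default 10) on the source
  preimage of cancer-gene spans, 1 elsewhere. Lengths are log-uniform on
  1–500 nt — the upper bound scales the real spread of insertion-site
  sizes down with the genome; with 0.8–1.6 kb genes, longer elements would
  make overlap counting itself (boundary capture) a first-order bias of
  the recovered fold even when the planted fold is 1. At these defaults
  the residual bias of the no-enrichment control is |log2 fold| ≈ 0.1.
* **Expression** is log-normal in log10 FPKM: lncRNAs N(0, 0.9), pc genes
  N(0.5, 0.9), cancer genes shifted +1.1 (an order of magnitude, as
  elevated expression of curated cancer genes motivates matched controls
  in the first place). A quarter of non-cancer genes draw from the high
  component too, reflecting that many non-census genes are highly
  expressed; this also gives the matcher a usable candidate pool in the
  upper bins.
* **Differential expression** is simulated directly at the results-table
  level (gene, cancer type, log2FC, FDR) rather than from read counts —
  the DE caller itself is out of scope and the pipeline only consumes its
  output format. Planted-DE genes receive |log2FC| ≈ 2 with FDR below the
  threshold in 1–3 of 20 cancer types; oncogenes go up and tumour
  suppressors down with probability 0.97; null records have
  log2FC ~ N(0, 0.3) and uniform FDR. Cancer genes are DE with
  probability 0.8, others 0.45.
* **SNPs** are placed with weight `snp_enrichment_fold` (default 4) on
  cancer-lncRNA exonic bases; **CNVs** target a cancer-lncRNA span half of
  the time, with 70% of calls below the 0.05 significance threshold.
* **Unannotated transcripts** are placed uniformly, so intergenic
  insertion sites hit them no more than chance — the pipeline's
  permutation test should and does come out non-significant on them.
* **Evidence tables** for the genome-scale bundle derive from the planted
  cancer lncRNAs (70% literature-curated, mutagenesis = genes actually hit
  by a planted insertion site, 20% CRISPRi). A second, genome-free fixture
  (`make_census_evidence`) reproduces the study-scale source structure —
  375 literature genes (261 og / 92 ts / 22 both), 123 mutagenesis genes
  21 of which overlap the literature, and 21 CRISPRi genes (4 literature,
  2 mutagenesis, 15 novel: 12 og / 3 ts) — whose integration arithmetic
  (492 = 375 + 102 + 15; 275 og / 95 ts / 22 both / 100 unknown) is an
  acceptance check.

What passing tests on this generator do **not** show: the genome has no
sequence, no GC or repeat structure, no clustered gene families, and the
chain is colinear with no inversions or duplications; insertion sites,
SNPs and CNVs are conditionally independent given the gene classes, whereas
real signals co-vary along the genome. Recovery of a planted fold therefore
validates the pipeline's accounting and inference, not its robustness to
correlated genomic covariates — that is exactly why the expression-matched
control machinery exists and is tested separately.

## Determinism and problem sizes

Every stochastic component takes a seed or a `numpy` Generator; the
pipeline splits one top-level seed into per-stage seeds via
`SeedSequence`, and the generator is byte-identical across reruns of the
same configuration. The acceptance script sizes its analyses as: 162,315
exact-test tables (all margins ≤ 30), 100 random intersection instances,
20 generator seeds per enrichment-recovery condition, 200 null datasets of
1000 permutations each, and 10 matching seeds — about half a minute in
total on one CPU.

## Known limitations

* `min_blocks` follows this package's stated interpretation; chains whose
  reference behaviour differs at extreme settings may disagree.
* The length-normalisation of insertion-site density uses the merged gene
  span by default; exon-body normalisation is available behind
  `length_mode="exonic"` and changes the denominator, not the ranking, on
  the synthetic data.
* The matcher's single global feasibility ratio can produce small control
  sets when the candidate pool is sparse exactly where the targets sit;
  the diagnostics (`feasible_ratio`, skipped bins) expose this, and the
  achieved KS distance should always be checked before using a matched
  set.
* p-values from the exact test are clipped at the smallest positive float;
  extremely enriched nt-scale tables report `5e-324` rather than 0.
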