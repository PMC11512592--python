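# Methods

`mitohet` re-implements, as a tested library, an ultra-deep mitochondrial
heteroplasmy analysis built around molecular-barcode capture sequencing:
barcode-grouped read families are collapsed into consensus reads by a
Bayesian merge, consensus reads that look like nuclear mitochondrial
segments (NUMTs) are flagged and removed, low-frequency minor alleles are
called through six quality filters, calls are annotated for region,
coding effect and predicted pathogenicity, and per-sample mutation counts
feed cohort-level statistics. A synthetic-data module generates read
families and whole cohorts with known ground truth so that every stage is
testable without any external sequencing data.

## Reference model

Coordinates are 1-based inclusive ("m." notation) on a circular genome.
The capture design aligns D-loop-spanning reads against a *shifted* frame
in which the final 120 bp of the circle are copied to the front; this frame
exists only at ingestion and every position is normalized back to the
canonical circle immediately. Because probe segments tile the whole shifted
frame, the 120 wrapped positions are covered by two segments and carry
roughly double depth; pileup accumulation simply adds both images.

Region classes are D-loop (control region), protein-coding, RNA-coding
(tRNA/rRNA) and other-coding, with low-complexity homopolymer tracts
(m.302–316, m.512–526, m.16184–16193 on the standard layout) as an
independent overlay. The D-loop span is not uniquely standardized; we adopt
the common m.16024–m.576 convention (it contains all three low-complexity
tracts) and make it configurable in the region TSV. Where protein genes
overlap (ATP8/ATP6, ND4L/ND4), the first gene in configuration order
provides the reading frame for effect calls.

Coding effects use the vertebrate mitochondrial genetic code (translation
table 2) via Biopython: light-strand genes are read on the reverse
complement, incomplete stop codons are completed with 'A' (polyadenylation
convention), and any annotated-start codon (ATA/ATT/ATG/…) reads as Met in
codon 1. Only single-nucleotide substitutions are modelled; indels are out
of scope throughout the package.

The package bundles two coordinate layouts: the standard 37-gene human
mtDNA region table (used with a user-supplied FASTA, or with a synthetic
16,569-bp sequence for self-contained runs) and a 2,000-bp miniature
circular genome (two protein genes, one per strand; one tRNA; one rRNA; a
300-bp wrapping "D-loop"; two low-complexity tracts) for fast tests.

## Consensus calling

For one reference column of a read family with observed bases `b_i` and
base alignment qualities `BAQ_i`, the likelihood of each nucleotide
hypothesis `NT` is

    p(read_i | NT) = 1 − ε_i        if b_i = NT,    ε_i = 10^(−BAQ_i/10)
                   = ε_i / 3        otherwise,

and the posterior over {A, C, G, T} uses a uniform prior, which cancels.
Products are computed in log space (large families underflow otherwise).
The consensus base is the posterior argmax with phred quality
`round(−10·log10(1 − p_max))`, clamped to [0, 93] so it stays
ASCII-encodable at offset 33.

Numerical choices:

- **BAQ floor 2** before the likelihood: a BAQ-0 base would have match
  likelihood 0 and veto any hypothesis; floored bases are effectively
  uninformative instead.
- **Ties** (posterior gap < 1e−9) become 'N' with quality 0; 'N' bases are
  invisible to mismatch counting, NUMT distances and pileups. Disagreeing
  mate pairs at equal quality are the main source of 'N's.
- **Mate overlap**: because the likelihood product factorizes over reads,
  merging mate overlap first and then merging across pairs equals pooling
  all reads in one product, except for the intermediate integer rounding of
  the two-stage variant. The default is the single joint product
  (`overlap_order="joint"`); `"overlap_first"` is available and the two are
  tested for agreement at high BAQ.
- Consensus MAPQ is the maximum MAPQ of the constituent pairs.

Two implementations exist deliberately: a per-family scalar path
(`build_consensus`) written for clarity, and a per-segment vectorized path
(`consensus_block`) used by the pipeline; the test suite asserts exact
agreement between them, and against an independent enumeration oracle on
all columns of ≤ 4 reads.

## NUMT filtering

A consensus read is flagged as a potential NUMT if its edit distance to any
known NUMT sequence of its capture segment is *strictly* lower than its
distance to the sample's major mtDNA sequence, or if its reads carried an
upstream NUMT annotation (in the real pipeline, from genomic alignment; in
the simulator, a configurable fraction of true NUMT families). Ties are not
flagged. 'N' positions are dropped from both strings before the distance.

The scalar operation computes true Levenshtein distance (edlib). The batch
path used by the pipeline counts positional mismatches instead: consensus
rows are full-span, coordinate-aligned, substitution-only sequences, for
which the two distances coincide; the equivalence is cross-checked in
tests. The NUMT database is an input (FASTA or TSV per segment, including
common-polymorphism variant copies); discovering NUMT loci from a nuclear
genome is out of scope.

## Variant calling

Consensus reads enter the pileup only if MAPQ ≥ 20, not NUMT-flagged, and
not carrying excess mismatches against the sample's **major sequence**
(> 5 for coding-region reads, > 8 for D-loop reads; a read's region is that
of its midpoint). The major sequence is the per-site plurality allele over
qualifying consensus bases, computed in two passes: a provisional major
seeds the mismatch/NUMT screens, the major is rebuilt from reads that pass,
and the screens are re-evaluated once against the final sequence. Exact
plurality ties and uncovered sites fall back to the reference allele.
Homoplasmic differences between major and reference are the sample's
haplotype and are reported separately, never as mutations.

Individual bases need quality ≥ 30 to be counted; the fraction of covering
bases with quality ≥ 30 is tracked *before* that cut (otherwise filter (i)
would be vacuous). The minor allele at a site is the most frequent allele
other than the major. Six filters are evaluated everywhere and recorded per
site:

1. depth ≥ 100 and ≥ 70% of covering bases at quality ≥ 30;
2. site not in a low-complexity tract;
3. minor count ≥ 5;
4. log-likelihood quality score ≥ 5. The score's functional form is not
   uniquely determined by its name; we use the phred-scaled binomial
   log10-likelihood ratio `10·[ℓ(p = max(VAF, e)) − ℓ(p = e)]` at the
   observed minor count, with `e` the platform error rate. It is 0 at
   minor count 0 and increases with the minor count at fixed depth.
5. duplicate concordance: with the 2×2 table {minor, non-minor} ×
   {duplicate-built, singleton-built}, a two-sided Fisher exact `P ≥ 1e−4`,
   VAF fold-change ≤ 5 between the strata (a zero VAF in either stratum
   counts as infinite fold-change and fails; no duplicate coverage fails
   outright), and duplicate-stratum VAF ≥ 0.2%;
6. exact Poisson error test: `P(X ≥ minor)` with
   `X ~ Poisson(e·depth)` must be `< 0.01/16569` (strict; the per-site
   Bonferroni over the full genome is kept as printed even on the
   miniature genome unless reconfigured).

The default error rate is `e = 2×10⁻⁴` (0.02%). A variant is *called* when
all six filters pass and its VAF (over all qualifying consensus reads) is
≥ 0.5%; the duplicate-only VAF has its own 0.2% floor inside filter (5).
The Fisher test is a vectorized hypergeometric enumeration (needed to
evaluate every candidate site of a genome in one pass); scipy's
implementation serves as the independent oracle in tests. A sample showing
≥ 11 called variants at known polymorphic coding-region sites is flagged as
likely contaminated with a second mtDNA haplotype and excluded from cohort
tables.

## Annotation

Each called mutation gets its region class, its coding effect, and a
pathogenicity verdict: pathogenic ⇔ non-synonymous AND (CADD phred > 20 OR
disease-associated) AND not a known population polymorphism (allele-level
match, i.e. on (position, allele)). The rule is restricted to the
protein-coding region, so tRNA/rRNA mutations are never labelled pathogenic
even when disease-associated; they are still reported with their
annotations. Lookup knowledge enters as versioned TSV tables; there are no
live database queries. In the rare case where the minor allele equals the
reference base (a back-mutation at a haplotype site), the codon change is
classified via the major allele — synonymy of a codon swap is symmetric.

## Synthetic data

The generator emulates the capture design, not the chemistry: probe
segments tile the shifted genome (46 by default); each segment yields
`depth` barcode families (default 4000, with ±20% lognormal per-segment
jitter); each family is one molecule. Molecules — not reads — carry the
heteroplasmy state: a molecule is mutant with probability VAF, duplicates
inherit it. The duplicate-pair count is 1 + Geometric, truncated at 10
pairs, with the geometric parameter set so that P(≥ 2 pairs) equals the
duplicate rate (default 0.5). Reads are 2×250 by default, covering the
segment from both ends; per-base BAQ is drawn from a configurable discrete
distribution (default: 30 with 90% mass, 20 with 10% — the pipeline's
quality cut sits at 30), and miscalls occur at `10^(−BAQ/10)` uniformly
over the other three bases. NUMT families replace a configurable fraction
of molecules with database entries (reference segments carrying 4–10 fixed
substitutions, plus variant copies with one extra polymorphism). Everything
is deterministic under a seed.

What the simulator does **not** model: capture-arm mispriming, chimeric
reads, alignment/realignment errors, quality mis-calibration, strand bias,
indels, and real NUMT phylogeny. Passing spike-in tests therefore show the
*statistical machinery* behaves as designed under calibrated qualities;
they do not certify performance on real sequencing artifacts.

Cohorts: per-sample mutation counts per category (D-loop, synonymous,
non-synonymous, RNA) are Poisson with optionally log-linear age slopes,
`λ = mean·exp(slope·(age − age_ref))`; positions are placed uniformly
within the category's candidate substitutions (low-complexity tracts
excluded, since calls there are filtered by design); heteroplasmy VAFs are
log-uniform on [1%, 10%] by default (detectable at study depth); a
per-group fraction of non-synonymous mutations is made pathogenic, and the
generator emits matching CADD/disease/polymorphism tables so annotation can
reproduce the truth. Haplotype variants double as the known-polymorphism
list, which also exercises the contamination screen.

## Cohort statistics

Group summaries are mean (min–max) per category. Between-group comparisons
use two-tailed homoscedastic (pooled-variance) Student's t-tests; group
labels can be pooled (e.g. all controls vs all carriers). Associations are
re-evaluated with age-adjusted logistic regression (case ~ count + age) or
its multinomial variant over disease stages, reporting odds ratios per unit
count with Wald two-tailed p-values. Age trends use a Poisson GLM
(log link) of count on age, reporting the slope per year with its SE.
P-values are unadjusted across categories; the only multiple-testing
correction in the pipeline is the per-site Bonferroni inside the caller.
Degenerate inputs (zero variance, empty outcome classes, perfect
separation, all-zero counts) raise a typed error rather than returning
numbers.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own verification design:

- Consensus equations: exhaustive enumeration of all columns of ≤ 4 reads
  with BAQ ∈ {10, 20, 30, 40} (symmetry fixes the first read's base).
- Filter fidelity: 10,000 randomized pileup sites on the full-size genome,
  against scipy/closed-form oracles.
- Spike-in study: 10 seeds (tests) / 3 seeds (acceptance script) of a
  full-size sample at 4000×, 20 heteroplasmies at VAF 1%, BAQ 30,
  duplicate rate 0.5.
- VAF-boundary study: 20 spikes at VAF 0.5% per seed on the miniature
  genome at exactly 1000× (no depth jitter, BAQ 40), 30 seeds in tests /
  10 in the script; compared to the exact Binomial(1000, 0.005) tail.
- Parameter recovery: 100 cohorts of n = 200 for CI coverage of a
  0.03/yr slope; 1000 null replicates for type-I calibration.
- Cohort reports: groups of 23/22/21 samples (pooled over repeated draws
  to stabilize means), D-loop mean 3.0 with slope 0.057/yr.

## Known limitations

- The "log likelihood quality score" (filter 4) is a documented functional
  choice; other monotone scores with threshold 5 would shift borderline
  calls.
- Whether the calling VAF uses all consensus reads or duplicates-only is
  ambiguous in the method's description; all-reads is used here, with the
  0.2% duplicate floor retained inside filter (5).
- The D-loop boundary convention affects D-loop vs coding tallies at the
  margins; it is configurable.
- Sensitivity/specificity figures are simulator-based (see above) and the
  bundled full-size genome is synthetic in sequence (real coordinate
  layout); runs on real data require a real reference FASTA and curated
  annotation/NUMT tables.
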