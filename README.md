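# mitohet

Ultra-deep mitochondrial DNA heteroplasmy analysis from molecular-barcode
capture sequencing: Bayesian consensus calling of barcoded read families,
NUMT filtering, six-filter low-frequency variant calling, functional and
pathogenicity annotation, and cohort-level mutation-incidence statistics —
plus a synthetic-data module that generates read families and whole cohorts
with known ground truth, so every stage is testable end to end.

## The problem

Heteroplasmies — minor mtDNA alleles present in a small fraction of a
cell's mitochondrial genomes — accumulate with age in post-mitotic tissues
such as skeletal muscle, and their burden is a readout of mitochondrial
genome maintenance. Detecting them below 1% variant allele fraction (VAF)
is dominated by two error sources: sequencing/PCR errors, and reads from
NUMTs (nuclear mitochondrial segments) that masquerade as low-level
variants. Barcoded capture designs solve the first by tagging each captured
mtDNA molecule with a unique molecular barcode: all reads sharing a barcode
(a *read family*) derive from one molecule, so merging them cancels
independent errors.

## The model

For a family's pileup column with observed bases `b_i` and base alignment
qualities `BAQ_i`, each nucleotide hypothesis `NT` has likelihood

    p(read_i | NT) = 1 − ε_i       if b_i = NT,   ε_i = 10^(−BAQ_i/10)
                   = ε_i / 3       otherwise

and the posterior over {A,C,G,T} (uniform prior, log-space product) gives
the consensus base with phred quality `−10·log10(1 − p_max)`, clamped to
[0, 93]. Consensus reads closer (edit distance) to a known NUMT sequence
than to the sample's own major sequence are discarded, as are reads with
MAPQ < 20 or excess mismatches (>5 coding / >8 D-loop). A minor allele is
called when it passes six filters — depth ≥ 100 with ≥ 70% of bases at
BAQ ≥ 30; not in a low-complexity tract; ≥ 5 minor reads; binomial
log-likelihood-ratio score ≥ 5; VAF concordance between duplicate-built
and singleton-built consensus reads (Fisher exact P ≥ 1e−4, fold-change
≤ 5, duplicate VAF ≥ 0.2%); exact Poisson error test at rate 0.02% with
P < 0.01/16569 — and its VAF is ≥ 0.5%. Cohort statistics reproduce the
standard analysis battery: group means with ranges, two-tailed
homoscedastic t-tests, age-adjusted (multinomial) logistic regression, and
Poisson regression of mutation count on age. See `docs/methods.md` for the
full account.

## Worked example

Simulate one sample on the bundled 2,000-bp miniature circular genome,
call variants, and inspect the result:

```python
import mitohet as mh

ref = mh.mini_reference()
panel = mh.make_panel(ref, 8)
truth = mh.TruthSet(
    heteroplasmies=[mh.Heteroplasmy(pos=500, alt="A", vaf=0.05)],
    depth=500, read_length=150, seed=7,
)
blocks = mh.simulate_families(truth, panel, ref)
cfg = mh.PipelineConfig(n_segments=8, depth=500, read_length=150, seed=7)
result = mh.process_sample(blocks, ref, None, cfg, "demo")
print(result.called[["pos", "minor", "minor_count", "depth", "vaf", "vaf_dup"]])
```

prints

```
    pos minor  minor_count  depth       vaf   vaf_dup
80  500     G           24    532  0.045113  0.045775
```

— the spiked 5% heteroplasmy at m.500 is recovered at VAF 4.5% (24 of 532
qualifying consensus reads; the duplicate-built stratum agrees), and no
other site survives the six filters. The same pipeline is available from
the shell (`mitohet simulate | consensus | call | annotate | stats | all`).

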