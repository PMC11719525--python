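# Methods

This note records the models, rules and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and the gene model

Internally all intervals are 0-based half-open on the forward genomic axis;
GTF I/O converts from/to 1-based inclusive at the boundary. Strand-aware
logic runs on *directed* coordinates (`d5`/`d3`), which negate positions on
the minus strand so that 5′→3′ comparisons use one code path. Transcripts
store exons and CDS segments in transcript orientation; every CDS segment
must lie inside exactly one exon (violations are validation errors naming
the transcript). When a GTF carries `tag "basic"` on any transcript, only
basic-tagged transcripts are used, matching basic-annotation inputs;
untagged GTFs keep all transcripts. Transcript IDs are compared to metadata
after stripping `.N` version suffixes.

## Exon classification

A *unique internal exon* is a deduplicated (chrom, start, end, strand)
interval that is neither first nor last exon in at least one transcript with
≥ 3 exons. An exon that is internal in one isoform but terminal in another
still counts as internal and is flagged `mixed_terminal` for audit; the
choice is a convention, since deduplicated exon sets do not distinguish the
two roles.

**Coding type.** Against the CDS span of a containing transcript, in
transcript orientation: entirely before the CDS → Type 1; containing the
CDS 5′ end strictly inside → Type 2 (5UC); entirely inside → Type 3;
containing the CDS 3′ end strictly inside → Type 4; entirely after →
Type 5. An exon containing the whole CDS is Type 2 (the initiation site
dominates); an exon that *starts exactly at* the start codon has no 5′UTR
portion and is not 5UC. When containing isoforms disagree (e.g. alternative
start codons), the fixed priority Type2 > Type4 > Type1 > Type5 > Type3
picks one label and the exon is flagged `type_conflict`. Exons contained
only in non-coding isoforms of a coding gene have no UTR/CDS composition;
they are dropped from the typed table and counted in the summary audit
fields.

**Splice class.** The *covering* isoforms of an exon are those whose genomic
span (first-exon start to last-exon end) contains it. Rules in order:

1. single-isoform gene, or exact-coordinate presence in every covering
   isoform → constitutive;
2. some covering isoform has an overlapping exon whose differing boundary is
   a genuine splice site (i.e. not that transcript's own 5′/3′ terminus)
   → SSE;
3. some covering isoform has no overlapping exon at all → ASE;
4. otherwise → other alternative usage.

The splice-site qualification in rule 2 is what separates a true
splice-site shift from overlap with an alternative *terminal* exon (whose
outer boundary is a transcription start or poly-A site, not a splice site);
without it the "other" class would be unreachable. SSE is tested before
ASE so that a boundary-variant exon that is also skipped in some isoform is
counted once, as SSE — the classes partition the exon set.

## PSI quantification

Skipped-exon events are enumerated per gene: for every run of three
genomically adjacent exons A–B–C in some isoform, an event exists when
another isoform joins A to C with the identical donor and acceptor. One
event is emitted per (exon, flank pair); IDs follow the SUPPA SE convention
and events are exported in ioe layout.

Junction PSI is `(u+d)/(u+d+2s)` with the value reported only when
`u+d+s > min_total` (default 50, strict). The threshold is interpreted as
the unweighted read total; it is a parameter. The skipping count enters the
denominator twice because an included exon copy produces evidence at *two*
junctions while a skipped copy produces one skipping read. Per-tissue PSI
is the median of per-sample PSIs (robust to depth outliers; the aggregation
is a choice). Tissue-ΔPSI subtracts each event's cross-tissue median;
events with fewer than 3 non-missing tissues are excluded. TPM-based PSI is
Σ inclusion-TPM / Σ event-TPM, missing when the denominator is zero.
Knockdown ΔPSI groups use the 0.2 bands with boundaries belonging to
UP/DOWN. GTEx-style junction IDs (`chrom_start_end`, 1-based inclusive
intron) are converted on read.

## Coverage enrichment

Coverage is a per-chromosome step function (bedGraph semantics); window
means are computed from the signal's cumulative integral, so fractional bin
edges (needed when an exon body is rescaled to 10 bins) are exact
length-weighted averages. The matrix is 50 upstream + 10 body + 50
downstream bins of 10 nt, rows column-reversed on the minus strand so
column 0 is always 5′-most, and all-zero rows are dropped.

Region enrichment pairs the two sets' per-bin median profiles: the fold
change is the median per-bin ratio (zero-denominator bins excluded; ratio
of medians available behind a flag) and the p-value is the exact Wilcoxon
signed-rank test on the paired profiles. Bin-level pairing is a choice —
the per-bin profile is the unit the meta-coverage matrix defines. Note the
exon region has only 10 paired bins, so its p-value cannot pass the
−log₁₀p > 6 cutoff by construction; the cutoff is designed for the 50-bin
flanks.

For ΔPSI stratification the upstream window is re-binned to 50-nt bins and
each exon contributes the *median of its 10 upstream bins* as one
observation to its group; groups are compared all-pairs by Steel–Dwass.
Using the exon as the sampling unit keeps observations independent (bins of
one exon are not) and gives the test the sample size the group sizes imply;
per-bin medians are still returned for boxplot display.

## Statistical tests

*Exact Wilcoxon signed-rank*: zeros dropped, midranks on ties; for n ≤ 25
untied differences the two-sided p comes from the full sign-assignment null
distribution (computed by convolution, identical to enumerating all 2ⁿ sign
vectors); otherwise a tie-corrected normal approximation with continuity
correction. The method used is recorded in the result.

*Steel–Dwass*: for each group pair, pooled midranks give the first group's
rank sum, standardised with the tie-corrected two-sample variance and
referred to the studentized-range distribution with k groups and infinite
degrees of freedom (q = |t|·√2). With k = 2 this reduces to the two-sided
normal-approximation rank-sum test (no continuity correction), which the
tests verify against an independent implementation. Constant pooled pairs
give p = 1.

*Ward clustering* follows the ward.D2 convention: Lance–Williams updates on
squared distances, heights reported on the distance scale, ties broken
deterministically toward the smallest original leaf index. Newick branch
lengths are height differences. Heights are monotone by Ward's reducibility.

## Ortholog sharing

`shared(A,B)` counts genes of A's set with at least one ortholog inside B's
set; the symmetrised count is the mean of both directions and the distance
is `1 − shared/(|A|+|B|−shared)` (a Jaccard form; both sets empty → 0).
The raw shared counts can be re-derived from the emitted maps, so other
metrics remain computable. Ortholog maps are consumed from 4-column TSVs;
live retrieval from annotation services is out of scope.

## The synthetic-data generator

The generator is the package's study-condition definition: three-exon gene
templates plant one focal cassette exon per gene with a known coding type
(CDS anchors placed per type; the start codon ATG and GT/AG splice
dinucleotides are planted in an otherwise i.i.d. uniform ACGT genome) and a
known splice class (single isoform → constitutive; flank-joining isoform →
ASE; internal 5′-splice-site variant → SSE; overlapping alternative first
exon → other). Splice-site variants necessarily come in clusters of two
internal exons, so SSE quotas must be even. Focal exon lengths are drawn
log-normally (σ = 0.35) around per-type medians of 122 nt, with 161 nt for
Type 2 — the observed size bias of initiation-site-containing exons. Each
artifact draws from its own RNG stream derived from the master seed, so
outputs are byte-reproducible and adding artifacts never perturbs others.

*Junction counts*: per event and sample, total reads n ~ Poisson(depth 200),
skipping reads s ~ Binomial(n, (1−π)/(1+π)), inclusion reads split evenly
between the two inclusion junctions. The skip probability reflects that an
included copy contributes two junction reads and a skipped copy one, which
makes the junction PSI estimator consistent for π (bias < 0.01 at
n = 10,000 in the tests). True PSIs are drawn from a bimodal mixture
(Beta(1.2,8) / Beta(8,1.2) peaks with a small uniform moderate component,
≈ 15% of mass in 0.3 < π < 0.75); ten tissues at five samples each, with
brain/muscle/testis given inclusion shifts (−0.25/−0.15/−0.15) to emulate
tissue-specific regulation.

*Coverage*: Poisson(λ = 8) background per 10-nt bin over each event exon's
locus ± 600 nt; bound exons' strand-aware upstream windows (500 nt before
the 5′ splice site) are scaled by the planted fold (default 1.5).

*Knockdown*: control TPMs encode PSI = π; under knockdown, bound events
gain `kd_effect` (+0.3) PSI — direct repression released by silencing — and
a configurable fraction of unbound events lose the same amount (indirect
targets), which is what populates the DOWN group of the stratified
comparison; isoform TPMs get log-normal noise (σ = 0.1).

*Species sets*: an ancestral pool of 300 genes (a realistic 5UC-ASE
gene-set scale) descends a planted tree; on a branch of length L each gene
survives with probability (1−loss)^L, and orthology is identity on shared
genes. The default tree is a balanced ultrametric 10-leaf topology. Balance
is essential, not cosmetic: Ward's variance criterion inflates distances to
large clusters, so a deeply nested caterpillar topology is unrecoverable
from sharing distances *even without sampling noise* (a singleton deep leaf
pairs with another singleton before joining a large clade). With the
balanced clock tree, recovery is 100/100 seeds at loss rates 0.15–0.2.

## What the synthetic tests do and do not show

Passing tests demonstrate that classification, event generation, PSI
arithmetic, the enrichment machinery and the clustering recover planted
truth under the generator's idealised conditions: clean annotations, exact
junction coordinates, Poisson/binomial sampling, independent loci. Real
data add annotation errors, overlapping genes, junction mis-mapping,
coverage autocorrelation, batch structure and non-identity orthology — none
of which the generator emulates. Quantities measured on synthetic data
(e.g. length medians, moderate-PSI fractions) characterise the generator's
planted distributions, not human annotation; the published human
classification counts ship as a reference table and are used for count
arithmetic only.

## Problem sizes and defaults

Default simulations use 210 genes (12 exons per type×class cell), 60
events, 10 tissues × 5 samples, 300 exons per enrichment set over 50 seeds,
and 100 seeds for tree recovery — sizes chosen so the full suite and the
acceptance script each complete in well under a minute of compute per
stage while keeping Monte-Carlo rates stable. All thresholds default to
the standard analysis settings (read total > 50, PSI band 0.3/0.75, ΔPSI
band 0.2, volcano cutoffs 0.4/6, windows 500/100/500 at 10-nt bins).

## Known limitations

* SSE detection requires boundary-variant exons to be internal somewhere;
  variants appearing only as terminal exons classify as "other".
* The exact signed-rank path requires untied |differences|; midrank ties at
  n ≤ 25 fall back to the normal approximation rather than an exact
  tie-permutation distribution.
* Steel–Dwass uses the asymptotic studentized-range reference; exact
  small-sample permutation is not implemented.
* Ward on sharing distances cannot recover strongly unbalanced topologies
  (see above); for such shapes a different linkage or a proper
  tree-inference method would be needed.
* TPM-based PSI trusts the isoform quantification; no uncertainty is
  propagated. Empirical significance calibration for condition ΔPSI is out
  of scope (point estimates with fixed bands are reported).
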