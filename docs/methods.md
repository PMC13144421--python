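# Methods

`diploscan` analyses *genic diploidization* — the decay of a polyploid
genome back toward diploid-like gene content.  After a whole-genome
duplication (WGD) every gene exists in two homoeologous copies; over time
one member of many pairs is deleted outright (fractionation, typically by
illegitimate recombination), disabled in place (pseudogenization by
premature stop codons or frameshifts), or displaced by a processed
retrocopy, while transposable elements (TEs) pile into introns.  The
package detects and quantifies these signals in an annotated genome and
ships a generative simulator that provides per-gene ground truth for every
stage.

## Coordinate and data model

All intervals are 0-based half-open on the forward genomic strand;
conversion to/from the 1-based closed GFF3 and RepeatMasker conventions
happens only at the format boundary, so GFF3 start/end columns round-trip
bit-exactly.  One `GeneModel` is created per mRNA; the longest mRNA of
each gene (ties by id) is the *predominant* model and is the only one used
for scoring — the analysis targets gene copies, not isoforms.  UTRs are not
modelled; gene span is the exon hull and fractionation is computed on CDS
only, because the object of study is coding ("genic") decay.

## WGD simulator

The simulator builds an ancestral gene complement (all-coding exons with
`ATG … TAA` CDS free of internal stops, exponential-ish intron and
intergenic spacer lengths), duplicates it into an A and a B chromosome set,
and then degrades it:

- **Divergence** — i.i.d. substitutions at `wgd_divergence` per site
  (default 0.03) with a 2:1 transition:transversion ratio, so K2P
  estimation is exercised with Q > 0.  CDS substitutions in *functional*
  copies are placed under purifying selection: a substitution that would
  create an internal stop codon is reverted.  Residuals of deleted genes
  decay without this constraint.  Without the constraint a few percent of
  intact copies acquire chance stops and are (correctly, but
  uninformatively) called pseudogenes.
- **Fractionation** — each B copy is deleted with probability `f`; A copies
  with `f × bias` (`bias` is the A:B deletion odds; the paper reports
  biased fractionation as plausible but unquantified, so the knob defaults
  to fully one-sided without asserting a literature value).  A deleted gene
  optionally leaves a truncated residual whose cut point is chosen so the
  residual retains a target fraction (uniform 0.10–0.45) of the *CDS* —
  matching the definition of a fragmented pseudogene (low coverage to
  parent, high identity).
- **Pseudogenization** — retained B copies are disabled with probability
  `p`, half by converting one internal codon to a stop, half by a 1–2 bp
  frameshift (the annotated exon interval absorbs the length change, as a
  real annotation would).
- **Retrocopies** — with probability `r` a processed copy (spliced CDS at
  1% divergence plus a 25 bp polyA tail) lands at a random intergenic slot.
- **Tandem duplications** (probability `t`) add an extra annotated family
  member next to the source copy.
- **TEs** — per intron and per spacer, Poisson(`λ`) insertions whose
  *annotated* Kimura divergences are drawn from a mixture of amplification
  waves (default 70% at 3 ± 1.5% and 30% at 25 ± 4%, a recent major wave
  plus an older one); the inserted sequence itself is random, emulating a
  RepeatMasker annotation rather than molecular evolution of the TE.
- **Inversions** — with probability `inversion_rate` per B chromosome, a
  run of 5–30 gene slots is reversed in rank order.

Each process draws from its own stream spawned from the master seed, so
enabling TE simulation does not perturb gene fates; outputs are
byte-identical across reruns.  The diploid outgroup is emitted as two
haplotypes each carrying every ancestral gene, so a family fully retained
in the diploidized tetraploid (H1+H2 in the haploid representation) counts
2 against an outgroup count of 2 — the convention under which loss of one
homoeolog yields retention exactly 0.5.

What the simulator does *not* emulate: selection differentials between
genes, recombination maps, nested/fragmented TE copies, sequencing or
annotation error, and UTRs.  Passing tests therefore demonstrate that the
algorithms recover the processes they model, not that real annotations are
this clean.

## Homoeolog pairing

Synteny is computed on the gene-rank scale (robust to TE-driven physical
size differences).  Cross-chromosome same-family gene pairs become
anchors; families larger than 8 × ploidy members are excluded as
promiscuous (the same overdispersion cap used for retention).  Within each
chromosome pair, maximal collinear chains (strictly monotone in both rank
coordinates, rank gaps ≤ `max_rank_gap` = 25) are extracted iteratively by
O(n²) longest-chain dynamic programming, in both orientations; blocks
below `min_block_size` = 5 anchors are discarded, so single-gene
transpositions cannot seed blocks.  Chromosomes are paired greedily by
summed block score (adequate because homoeologous signal dominates;
optimal matching would matter only for near-tied pairings, a documented
limitation).  Within a pair the member with more repeat-covered bp is
labelled H2 — the convention is fixed but arbitrary, and the test suite
asserts every downstream statistic is invariant to a label swap.

A gene strictly between two consecutive block anchors whose family has no
member in the corresponding partner-side rank window is linked "lost";
requiring flanking anchors on both sides prevents miscalling block edges
as losses, at the price that losses at the first/last anchor of a block
are left unplaced rather than called.

## Pseudogene scan

High-confidence parents require identity > 40% and query/subject coverage
> 50% (strict) against a curated protein set (BLOSUM62 local alignment; in
tests the simulator's ancestral proteome serves as the curated set).
Rather than a genome-wide six-frame search, candidates come from two
sources with identical downstream semantics: annotated genes aligned
against their positional homoeolog (only the lower-identity copy of an
eligible pair is scanned against the higher-identity one, so a disablement
in one copy cannot flag its intact partner), and gene-free windows located
by exact 16-mer seed matches to a parent CDS (stride 10, hits clustered
into windows).  At ≤ 5% divergence a ≥ 45 bp fragment carries enough
exact seeds that misses are rare.

Candidate loci are aligned with affine-gap local alignment (match +2,
mismatch −3, gap open −5, gap extend −2; a gap of length L costs
open + (L−1)·extend), delegated to `Bio.Align.PairwiseAligner` and checked
in the tests against an independent Gotoh DP.  Evidence is then read off
the alignment:

- **premature stop** — an in-frame stop codon in the locus at a parent
  codon strictly before the parent's own stop (codons spanning indels are
  skipped);
- **frameshift** — a junction indel with length mod 3 ≠ 0 and shorter
  than 40 bp (longer gaps are structural — introns — never frameshifts);
- **polyA** — ≥ 24 adenines in a 30 bp window within 50 bp downstream of
  the alignment end (the rule is fixed here because upstream tools leave
  it unstated; all three thresholds are module constants).

Classification is deterministic: PSSD when polyA is present or when the
alignment spans at least one parent CDS-segment junction contiguously
(intron loss; requires ≥ 50% parent coverage, since a fragment barely
crossing one junction cannot support the claim — for annotated candidates
contiguity is judged from the candidate's own exon count); otherwise FRAG
when coverage < 0.5 with identity ≥ 40%; otherwise DUP.  No call is made
without at least one evidence item, asserted on every run.  Fractionation
of a gene is 100 × (1 − coverage) of its CDS by the homoeologous locus
(gene, or surviving pseudogenic region when the link is "lost"); unplaced
genes are not computable and are excluded from family means rather than
imputed.

## Scores, retention, filters

Genome-wide z-scores (sample sd, n−1) of intron bp and intronic-repeat bp
are computed over *all* predominant gene models, zeros included — excluding
intron-less genes would inflate the z of modest insertions.  Intronic
repeat bp merges overlapping repeats across classes (a bp is
intronic-repeat once); landscape binning merges within (class, bin) and
normalizes by total assembly length (mappable-length normalization is the
noted alternative).  Family × group records take the max z over copies,
the mean fractionation, and the summed disablement count; a record is
*highly affected* iff max intronic-repeat z ≥ 1 (inclusive) or
disablements > 0.  Fragmentation without any disablement does not count
as "evidence of pseudogenization" (configurable).  Retention is
1 − (#Outgroup − #Group)/#Outgroup, requiring ≥ 1 outgroup member; values
above 1 mark expansions; families with more than 8 × ploidy members per
group are dropped; orthogroups qualify as families when at least half of
the sampled species are present (ceiling rule).

## Motif scanning

Promoters are the 1.5 kb upstream of the annotated TSS (the 5′ gene end),
truncated at contig edges, reverse-complemented for minus-strand genes.
Scanning is log-odds (base 2) against a 0-order background with a small
pseudocount; p-values come from the exact distribution of *discretized*
window scores (1/1000 of the score range per bin) under the background,
computed by dynamic programming over motif columns — both the window score
and the distribution use the same integer scores, so p-values are exact
with respect to the discretized scoring and monotone non-increasing in
score by construction.  Windows containing N never hit.  Both strands are
scanned with separately computed distributions (they differ under an
asymmetric background).  The evening-element consensus used in tests
(AAAATATCT) is standard circadian-literature material shipped as a test
fixture, not a measured matrix.  The positional window for
presence/absence matrices is a required argument: "the particular
position" of an element is study-specific.

## Assays

The C-value is the exact flow-cytometry peak ratio times the internal
standard (e.g. *Pisum sativum*, 4.42 pg/1C): degree 0 in intensities,
degree 1 in the standard.  Net assimilation is assimilation − respiration;
gas-exchange smoothing averages 5-record blocks after clamping negative
conductance to zero (instrument artefact correction).

Titratable acidity converts each titration step's 615/445 absorbance ratio
to pH via monotone piecewise-cubic (PCHIP) interpolation of the buffer
standards (linear optionally), isotonically corrects a non-monotone trace
with a warning, finds the first volume V\* reaching pH 7.0 by linear
interpolation between bracketing steps, and scales: TA = V\*·[NaOH] ×
(extract/aliquot volume) / tissue mass, reported explicitly as µmol H⁺ per
g fresh weight.  The forward oracle titrates a malate-like diprotic acid
by charge balance with dilution and a sigmoid indicator response.  With
the standard protocol (10 µL aliquot, 10 mM NaOH, 1 µL steps) the endpoint
falls near 12 µL for a typical dark-period extract, so one step is ~8% of
V\*; interpolation reduces the recovery error to ~3–4%, and the assay's
sensible operating range starts around 3 µmol of extract H⁺ (~30 steps).
Below that, step quantization dominates.

## Problem sizes

The shipped tests and the acceptance script run desk-scale scenarios
chosen to estimate each property stably: 1,000-gene-copy simulations
(2 × 250 ancestral genes) over three seeds for class recovery, 2,000
families for the retention signature, 900-link genomes for homoeolog
recovery, 500 constructed truncations, 10 kb sequences for K2P, all 4^w
words for motif widths ≤ 8, and 100 random titration curves.
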