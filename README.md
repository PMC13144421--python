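# diploscan

Genic diploidization analysis for post-polyploid plant genomes.

After a whole-genome duplication (WGD), a genome slowly returns toward
diploid-like gene content: one member of many homoeologous gene pairs is
deleted (*fractionation*), disabled in place by premature stop codons or
frameshifts (*pseudogenization*), replaced by an intronless processed
retrocopy with a polyA tail, or buried under transposable-element (TE)
insertions in its introns.  In CAM plants such as *Clusia*, this decay has
been linked to the loss of specific metabolic capacities — e.g. the
phosphorolytic route of chloroplastic starch degradation — and hence to
the diversity of photosynthetic physiotypes.  `diploscan` is a toolkit for
detecting and quantifying these signals, aimed at comparative genomicists
working on diploidized polyploids.

It provides:

- **genome_io** — GFF3/FASTA/RepeatMasker-`.out`/TSV readers and writers
  around a shared `GenomeBundle` data model (0-based half-open internally,
  bit-exact GFF3 round-trips).
- **simulate** — a WGD genome simulator: two homoeologous chromosome sets
  with tunable divergence, fractionation (with decaying residuals),
  stop/frameshift pseudogenization, retrocopies, tandem duplications,
  inversions, and intronic TEs dated by one or two amplification waves;
  emits FASTA + GFF3 + `.out` + family TSV plus a per-gene truth table.
- **homoeology** — synteny blocks by longest-chain dynamic programming on
  gene rank order, greedy chromosome pairing, H1/H2 assignment by
  repeat-affected size, and positional-homoeolog links (partner / lost /
  unplaced).
- **pseudogenes** — parent selection (identity > 40%, coverages > 50%),
  affine-gap local alignment of parents to annotated and seed-located
  unannotated loci, disablement calls, and the three-way classification
  DUP (duplicated, disabled in place) / FRAG (fragmented: low coverage,
  high identity) / PSSD (processed: intron loss and/or polyA), plus
  per-gene fractionation versus the partner homoeolog.
- **repeats** — Kimura-2-parameter distances,
  K = −½ ln[(1 − 2P − Q)√(1 − 2Q)], copy-divergence landscapes, and
  intronic-repeat burdens.
- **scoring** — genome-wide z-scores, family × homoeologous-group records
  with the "highly affected" flag (max intronic-repeat z ≥ 1 or
  disablements > 0), family retention against a diploid outgroup
  (1 − (#Outgroup − #Group)/#Outgroup) with the 8 × ploidy overdispersion
  filter and the half-of-species family rule.
- **motifs** — promoter extraction (1.5 kb upstream of the TSS) and PWM
  scanning with exact score-distribution p-values (e.g. the circadian
  evening element), presence/absence matrices across homoeologous groups.
- **assays** — flow-cytometry 1C values, net CO₂ assimilation, and
  titratable acidity from two-wavelength titration curves.

## Worked example

Simulate a diploidized tetraploid (2 × 100 ancestral genes, 3% homoeolog
divergence, 20% fractionation, 15% pseudogenization) and run the pipeline:

```python
from diploscan import (SimulationConfig, simulate, homoeolog_map,
                       select_parents, scan_pseudogenes, score_pipeline)
from diploscan.pseudogenes import translate_cds

cfg = SimulationConfig(seed=42, n_chromosome_pairs=2, genes_per_chromosome=100,
                       wgd_divergence=0.03, fractionation_prob=0.2,
                       pseudogenization_prob=0.15, retrocopy_prob=0.05,
                       residual_prob=0.6, te_insertions_per_intron=0.4)
bundles, truth = simulate(cfg)
focal, outgroup = bundles["focal"], bundles["outgroup"]

hmap = homoeolog_map(focal)
print("chromosome pairs:", hmap.chromosome_pairs)
print(f"genes linked: {sum(v != 'lost' for v in hmap.gene_links.values())},",
      f"lost: {sum(v == 'lost' for v in hmap.gene_links.values())}")

curated = {g.family_id: translate_cds(g.spliced_cds(outgroup.sequences))
           for g in outgroup.genes if g.gene_id.endswith("_O1")}
parents = select_parents(focal, curated)
calls = scan_pseudogenes(focal, hmap, parents)
from collections import Counter
print("pseudogene classes:", dict(Counter(c.pg_class for c in calls)))

records = score_pipeline(focal, hmap, calls)
print(f"family x group records: {len(records)},",
      f"highly affected: {sum(r.highly_affected for r in records)}")
```

Output:

```
chromosome pairs: [('chr00A', 'chr00B'), ('chr01A', 'chr01B')]
genes linked: 322, lost: 38
pseudogene classes: {'DUP': 30, 'PSSD': 13, 'FRAG': 23}
family x group records: 361, highly affected: 84
```

The two chromosome sets are correctly paired; 38 genes have lost their
positional homoeolog (fractionation); the pseudogene calls split into
disabled duplicates, fragments of deleted genes, and processed
retrocopies; and 84 family × group records are flagged highly affected
(intronic-repeat z ≥ 1 or disablement evidence) — the same summary a real
genome would yield, here with ground truth to check it against.

The same stages are available from the shell:

```bash
diploscan simulate --seed 42 --out run/
diploscan homoeologs --gff run/genes.gff3 --fasta run/genome.fa \
    --families run/families.tsv --repeats run/repeats.out --out run/map.tsv
diploscan score --dir run/ --ploidy 2 --out run/records.tsv
diploscan assay cvalue --fi-object 38 --fi-standard 100 --c-standard 4.42
```

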