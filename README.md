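# condelscan

Comparative-genomics screen for **conserved sequence deletions (CONDELs)**:
reference-genome intervals that are deeply conserved in species with a
complete ancestral trait, yet recurrently deleted in independent lineages
that have lost the trait.  The motivating application is fin reduction in
percomorph fishes — pelvic- and caudal-fin loss that evolved repeatedly and
maps to recurrent deletions near fin-development genes — but the machinery
is trait-agnostic: it consumes UCSC pairwise alignment chains against one
reference, a gene annotation, and a species table assigning each query
genome a role (*outgroup* = trait-complete, *target* = trait-reduced, with
targets grouped into clades).

## The screen

For each reference gene mapped confidently (second-best-chain-ratio ≥ 10
or gene-in-synteny support ≥ 10) to at least 17 outgroups and 5 targets,
the interval ±200 kb around the canonical-isoform TSS (400,001 bp) is
scanned for bases where

1. a **valid chain gap** (sequence missing in the query; not attributable
   to an assembly N-gap within 100 bp on the query side) is present in at
   least ⅔ of the species of *every* screened target clade, and
2. the base is covered by **conserved elements** in ≥ 17 outgroups, where a
   species' conserved elements are its top percent-identity sliding
   windows (10/25/50/100 bp, step 1, within ungapped alignment blocks)
   down to the identity cutoff at which their merged footprint covers 5%
   of the reference, ties included as a class.

Intersection pieces ≥ 20 bp are raw candidates; pieces within 20 bp merge;
merged pieces ≥ 50 bp that overlap a chain gap in at most one scorable
outgroup survive as final candidates.  Candidates reached from several
nearby genes are deduplicated by exact interval, keeping all gene links.

The package also implements the surrounding statistics: **Boschloo's
unconditional exact test** for 2×2 genotype–phenotype outcome tables
(statistic = one-sided Fisher exact p of the observed table; p-value =
sup over the nuisance success probability π of the chance of a table at
least as extreme under two independent binomials; two-sided doubles the
smaller side), Welch's *t*, Mann–Whitney *U* with exact small-sample
enumeration, phylogenetic GLS means under Brownian motion
(μ̂ = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹y with V the shared root-to-tip branch length),
patristic distance matrices, and JASPAR PWM scanning with relative match
scores on a 0–1000 scale.

## Worked example

Everything is testable offline through the synthetic-data generator, which
emits a complete bundle (reference FASTA, per-species genomes and chains,
BED12 gene models, species table, tree, truth table) with planted
conserved elements and clade-specific deletions:

```console
$ condelscan simulate --out demo --seed 7
wrote bundle to demo (20 planted CONDELs)

$ condelscan screen --config demo/screen_config.yaml --out demo_results
20 unique CONDEL candidates -> demo_results

$ head -3 demo_results/candidates.tsv
chrom  start  end    length  linked_genes                               clade_support      conservation_count  violations
chr1   10027  10210  183     gene01,gene02,gene03,gene04,gene05,gene06  cladeA:4,cladeB:3  17                  0
chr1   14170  14382  212     gene01,gene02,gene03,gene04,gene05,gene06  cladeA:4,cladeB:3  17                  0
```

The 20 recovered intervals coincide with the 20 planted loci in
`demo/truth.tsv` (`condel01` is `chr1:10027-10210`, deleted in every
species of both screened clades and conserved in all 17 outgroups):
precision and recall are both 1.0.  Columns report the interval, its
length, every gene whose ±200 kb window called it, per-clade deletion
support, the number of outgroups conserved across it, and outgroup
violations.

The exact test used for genome-editing outcomes (14 affected among 175
edited fish vs 1 among 236 controls):

```console
$ condelscan stats boschloo --table 14 161 1 235
{"statistic": 4.401786783388154e-05, "pvalue": 3.549889607697958e-05}
```

i.e. the association between editing and phenotype is significant with a
two-sided unconditional exact p ≈ 3.5 × 10⁻⁵.

Other subcommands: `orthology`, `gaps`, `conserve` (per-stage tracks),
`msa` (reference-anchored gapped alignment of a candidate), `pwm-scan`,
`stats welch`, `stats mwu`.

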