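# Methods

## Model and procedure

The screen treats a pairwise alignment chain as the unit of orthology
evidence between one reference genome and one query species.  Within a
chain, ungapped blocks witness sequence that survives in the query;
inter-block reference gaps (`dt > 0`) witness sequence missing from it.  A
CONDEL candidate is a reference interval where missing-ness co-occurs
across independent trait-reduced clades while deep conservation holds
across trait-complete outgroups — the forward-genomics association that
links a genotype (deletion) to a phenotype (trait reduction) without any
per-species functional data.

All coordinates in the package are 0-based half-open, the native frame of
both the chain and BED formats, so no stage shifts coordinates.  Chains
with a `-` query strand keep the format's reverse-complement query frame
internally; query-side sequence lookups convert to forward-strand
coordinates at the last moment.

### Stage order and assumptions

1. **Orthology** — per (gene, species), chains are scored by chain score ×
   fraction of the canonical (longest, ties by smallest transcript id)
   isoform's exonic bases covered by blocks.  The best chain is accepted
   when best/second-best score ratio ≥ 10 (a sole candidate counts as
   ratio ∞) *or* when ≥ 10 of the up-to-20 nearest flanking genes share
   the same best chain.  The disjunction, the overlap weighting and the
   10-per-side neighborhood are this package's interpretation of the
   two-threshold filter; all three are exposed
   (`ratio_thresh`, `synteny_thresh`, `require_both`,
   `n_neighbors_per_side`) because the upstream definition admits a
   conjunctive reading.
2. **Chain gaps** — one record per junction with `dt > 0`; `dq = 0` marks a
   single-sided (clean-deletion) gap, `dq > 0` a double-sided one.  A gap
   is invalidated when an assembly N-run (≥ 6 consecutive N, i.e. "more
   than 5") lies within 100 bp of its query-side context, measured on the
   forward strand of the query assembly — the only frame in which N-runs
   exist.  Invalidation drops the whole gap (`gap_exclusion_mode: drop`);
   a per-interval filter naturally excludes whole records, and partial
   trimming would manufacture gap boundaries with no alignment evidence.
   Valid gaps merge within (never across) chains at ≤ 20 bp.
3. **Conserved elements** — percent identity is computed in sliding
   windows of 10/25/50/100 bp at step 1, entirely inside single blocks:
   identity across an indel is undefined in a block model, and step 1
   makes the window set a deterministic function of the blocks.
   Identity is case-insensitive (soft-masking influenced the upstream
   aligner, not the identity of an aligned base) and N never matches.
   Windows are ranked by identity only; the selection admits whole tie
   classes in descending order until the merged union of admitted windows
   reaches 5% of the reference length, so the output is independent of
   sort stability.  Per chain, selected windows within 20 bp merge into
   elements.
4. **Screen** — the scan window is TSS ± 200,000 bp inclusive of the TSS
   base (unclipped length 400,001 bp); the TSS is `tx_start` on `+` genes
   and `tx_end − 1` on `-` genes.  The deletion consensus requires, at
   every base and for every screened clade, valid gaps in
   ≥ ⌈⅔ · clade size⌉ members, with the denominator counting all
   configured clade species (a species without an orthologous chain
   contributes no gap but still dilutes its clade).  Conservation requires
   per-base coverage by elements of ≥ 17 outgroups.  Intersection pieces
   ≥ 20 bp are raw candidates, merged at ≤ 20 bp, kept at ≥ 50 bp, and
   finally an outgroup "violation" — a valid gap overlapping the candidate
   in an outgroup whose confident chain fully spans it — is tolerated at
   most once.  Deduplication across genes is by exact interval equality:
   all per-gene scans consult the same global tracks, so a shared region
   yields identical coordinates from every calling gene; a fuzzy collapse
   is deliberately not the default.

### Association statistics

*Boschloo's exact test.* The statistic is the one-sided Fisher exact
p-value of the observed table; the p-value is the supremum over the
common success probability π ∈ (0,1) of the probability that two
independent binomials yield a table with a Fisher p no larger than
observed.  Following the reference implementation this field standardly
uses, the binomial pair is formed on the **outcome columns** of the
passed table (`condition_on="columns"`); conditioning on the group-size
rows is available as `condition_on="rows"`.  The supremum is evaluated on
a 10,001-point grid with bounded local refinement (observed agreement
with a 20,001-point brute-force sweep: better than 1e-9 on small tables).
The two-sided p doubles the smaller one-sided p, capped at 1, and reports
that side's statistic.  A table whose outcome column is all zero returns
p = 1 (no variation; every table is equally extreme).

*Phylogenetically corrected means.* GLS under Brownian motion on a
branch-length tree: V[i,j] is the shared root-to-tip path length,
μ̂ = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹y.  Unvalued tips are pruned, which provably leaves
the estimate unchanged.  `phylo_welch_t` combines the two groups'
corrected means with dispersion taken from the raw per-species values
(each sample is recentered on its corrected mean before a classical
Welch test); this recipe is an interpretation — the corrected-mean
comparison is defined up to how group variance is estimated — and is
flagged as such.

*Mann–Whitney U.* Exact p by the Gaussian-binomial rank-count recurrence
when m + n ≤ 20 without ties; otherwise the normal approximation with tie
and continuity corrections.

*PWM scanning.* JASPAR count matrices become log-odds against a uniform
0.25 background with a total pseudocount of 0.8 split by background (both
configurable; the upstream tool's constants are not published with the
procedure).  The relative score rescales a window's log-odds between the
matrix's attainable minimum and maximum onto 0–1000; hits require ≥ 925
on either strand, and windows containing N are skipped.

## Synthetic data: what it emulates, and what it does not

`simulate_dataset` plants the statistical structure the screen assumes:
conserved elements as low-substitution islands (rate 0.001/site/species)
in a neutral background (0.02), CONDELs as those islands additionally
deleted in the screened target clades, small background indels
(10⁻⁴/site, 1–10 bp), assembly N-runs (optionally placed just inside the
100 bp exclusion distance of a deletion junction to exercise that rule),
and every fifth query genome stored reverse-complemented with a `-`
strand chain.  Chains are emitted directly from the known simulated edits
— no aligner runs — so tests isolate the screen's logic from alignment
heuristics.  Default conditions: one 120 kb reference chromosome, 17
outgroups, screened clades of 4 and 3 targets, 20 planted CONDELs of
60–300 bp, 25 conserved elements without deletions, 6 genes.  Layout
coordinates come from a dedicated `layout_seed`, noise from `seed`, so
changing the seed re-rolls substitutions but not the planted geometry;
a given (config, seed) pair is byte-reproducible.

Deliberately absent: rate heterogeneity beyond the two classes,
inversions and translocations, alignment errors, fragmented assemblies
(one chain per species), and realistic gene structure.  Passing the
end-to-end recovery test therefore demonstrates the correctness of the
screen's set algebra, filters and conventions under its own model — not
robustness to aligner artifacts or assembly fragmentation in real
genomes.

A note on the interplay of two thresholds: with exactly 17 outgroups and
a 17-outgroup conservation floor, an outgroup carrying a whole-locus
deletion removes the locus from the conserved footprint before the
violation filter ever sees it.  Tolerating *v* violations is only
observable with at least `min_outgroups + v` outgroups; the violation
tests therefore use a 19-outgroup roster.

## Numerical choices and degenerate inputs

- Interval merging uses gap = next start − previous end; gap ≤ `max_dist`
  merges, so touching intervals always merge and `max_dist = 20`
  includes exactly-20 bp separations.
- Multi-track coverage is an event sweep (verified against per-base
  counting on ≤ 100 kb instances); per-species tracks are flattened first
  so one species never counts twice at a base.
- The window-selection quota compares the flattened union against
  `coverage_frac × genome length`; if the total window footprint cannot
  reach the quota, all windows are kept with a warning rather than an
  error.
- Requesting coverage by more species than tracks warns and returns
  empty rather than raising: an under-populated roster is a data
  condition, not a programming error.
- Chain parsing validates block sums against both header spans and
  reports the offending line; writing is a bit-exact inverse (records
  separated by single blank lines, no trailing blank line).
- Boschloo comparisons of Fisher statistics use a 1e-12 relative guard so
  tables that are mathematically tied are not split by float noise.

## Known limitations

- The orthology filter interprets a two-threshold criterion whose exact
  upstream definitions are not restated in the procedure it follows;
  results at `ratio ≈ 10` boundaries depend on that interpretation.
- `extract_condel_msa` is reference-anchored: query insertions are
  reported in a side channel rather than columnized, so the output is a
  genotyping aid, not a realignment.
- The screen holds all per-species window tables in memory; for
  chromosome-scale mammalian genomes the conserved-element stage would
  need chunking by chromosome.
- Patristic distances and tree parsing delegate to dendropy; trees with
  unlabeled or duplicate tips are rejected rather than repaired.
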