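# Methods

This note documents the models, parameter choices and numerical conventions
behind `microcensus`, and what the synthetic-data tests do and do not show
about real data.

## Novelty binning

A query's novelty is defined by the percent identity of its optimal local
alignment to the single most similar cultured 16S sequence. The normative
ladder has two cutoffs — genus 96.6%, phylum 86% — chosen as the upper 95%
confidence bound of the median within-rank 16S identity. Boundary semantics
are deliberately asymmetric and exact: "more than 96.6%" is strict, "at
least 86%" is inclusive, so both 96.6 and 86.0 fall in the middle
(uncultured genus-to-class) bin. Identities are compared at full floating
precision; there is no pre-rounding. A finer rank ladder
(species/family/order/class) is supported by `assign_level` but ships with
no default values, because intermediate cutoffs are study-specific;
comparison is strict at every level except the broadest, which is
inclusive, mirroring the two normative rules.

## Top-hit search

`align_pair` is an affine-gap Smith–Waterman (Biopython's
`PairwiseAligner`, local mode) with match +2, mismatch −3 and a gap of
length *k* costing 5 + 2*k* — megablast-like values, adopted because the
upstream BLASTn protocol this emulates does not pin parameters. Percent
identity is identical columns divided by **all** alignment columns,
gap columns included (standard BLAST identity reporting);
`query_alignment_length` is the number of query bases the local alignment
spans. `N` never matches anything, including another `N`.

`best_cultured_hit` ranks references by shared-*k*-mer count (default
*k* = 12), aligns the top *m* = 50, and returns the maximal-score hit; ties
break by higher identity, then lexicographically smaller subject id — a
fixed convention where the underlying protocol says only "single most
closely related". Queries sharing zero *k*-mers with every reference are
reported as no-hit. Prefilter recall is exact in the test regime (queries
derived from references share hundreds of *k*-mers; unrelated 1,000 bp
random sequences share almost none); the oracle tests quantify agreement
with brute-force dynamic programming when the prefilter is wide open.

The test oracle is an independent pure-Python three-state DP that
enumerates *all* co-optimal alignments; the implementation must achieve the
oracle's optimal score and report an (identity, columns, span) summary
realized by some optimal alignment. This avoids coupling the test to either
side's traceback tie-breaks.

## Retention (QC) rules

Rules run in a fixed order — minimum length → no hit → short alignment →
chimera → non-target — and each record is attributed to the first rule
that removes it. The retained set is order-independent; only attribution
depends on order. All thresholds are strict inequalities: amplicons must
exceed 900 bp (archaea) / 1,200 bp (bacteria), assembly-derived genes 900
bp; top-hit query alignments of exactly 300 bp are retained, 299 bp are
removed; alignment coverage of exactly 0.90 is retained by the chimera
rule. A record is chimeric only when its alignment spans <90% of the query
against the best cultured hit **and** against the best environmental-
database hit; an environmental no-hit counts as zero coverage. Records
without a taxonomy string pass the non-target filter with a logged
warning — that filter applies to classified sequences only.

## Aggregation

Count mode: fraction = sequences per bin / total, within any grouping
(environment alone, or environment × domain × dataset type — dropping
the domain key merges bacteria and archaea). Depth-weighted mode: within
each metagenome, fractions are read-depth sums per bin over total depth;
the environment value is the **unweighted arithmetic mean** of the
per-metagenome fractions. A regression test pins this mean-of-fractions
semantics against the pooled-counts alternative, which differs whenever
metagenome sizes differ. Metatranscriptomes carry no scaffold depths and
always use count mode. No minimum per-metagenome sequence count is
applied. Fractions carry no confidence intervals; the upstream protocol
reports none, and the dominant uncertainties (extraction bias,
environment cell totals) are not sampling errors.

## Global census

Cells per bin = environment cell total × bin fraction, summed over
environments. The default copy-number model is a single 16S gene copy per
genome; this is conservative because archaea — enriched in the novel bins —
average fewer copies (1.8) than bacteria (3.8), so applying the per-domain
means (the `domain_means` mode, which divides each domain's gene fraction
by its copy number and renormalizes) only increases the uncultured share.
`domain_means` requires domain-resolved fractions and refuses to guess a
bacteria:archaea split from combined fractions.

Display conventions, inferred from the published tables the fixtures
reproduce: percentages are rounded half away from zero; headline cell
counts are reported to two significant figures. Row percentages use the
row's own cell-count sum as denominator. The bundled census tables store
per-bin **cell counts** rather than percentages because printed
percentages are rounded and cannot regenerate the counts; conversely, in
rows whose printed counts are themselves rounded to one decimal (the
freshwater/plant/animal rows, and the soil metatranscriptome row, where
the printed integer count and the printed percentage are mutually
inconsistent) the fixture stores counts at the precision implied by the
published percentages, chosen so that both the printed counts and all
printed percentages regenerate under the conventions above. The published
totals row exceeds the sum of its printed rows by ~0.02% (the original
arithmetic used unrounded inputs); percentages and two-significant-figure
headlines are robust to this.

## Synthetic communities

The generator emulates the *statistical* structure the analysis assumes,
not 16S biology:

- **References**: i.i.d. uniform ACGT (default 1,500 bp; the simulated
  study conditions use 1,000 bp metagenome-type records, which satisfy the
  >900 bp gene rule and keep alignment cost proportional to L²).
  Unrelated references are ~25% identical — far below any cutoff.
- **Queries**: a reference with an exact number of substitutions
  (`round((1 − p/100)·L)`), no indels, so true identity is known to within
  1/(2L). Substitutions avoid 10 bp at each end, because local alignment
  would trim terminal mismatches and bias measured identity upward.
- **Identity ranges** per bin default to (97, 100), (86.5, 96.5) and
  (75, 85.5): at least 0.4 points inside the cutoffs so substitution-count
  rounding can never flip a truth bin, and bounded below at 75% so the
  per-column score drift (5p − 3 at identity p) stays strongly positive
  and local alignments of clean queries remain full length — the same
  rationale as the protected ends. Truth bins therefore equal
  `assign_bin(true_identity)` by construction, and measured identity
  equals true identity up to sub-0.5-point alignment effects.
- **Allocation**: per-sample bin counts use deterministic
  largest-remainder apportionment so small fixtures have exact
  composition (300 × 0.2/0.3/0.5 → 60/90/150); a multinomial mode exists
  for stochastic composition.
- **Chimeras** splice two distinct references at a breakpoint drawn
  U(0.25, 0.75); since parents are ~25% identical, alignment to either
  parent cannot profitably extend past the breakpoint, so query coverage
  ≈ max(b, 1−b) ≤ 0.75 < 0.9 against both databases.
- **Short fragments**: 150–290 bp of a lightly mutated reference
  (identity U(90, 99)) embedded in random flanks at full length — they
  pass the length rule but trip the <300 bp alignment rule, as intended.
- **Read depths**: log-normal (default μ=1, σ=1 on the log scale),
  clipped below at 1 — strictly positive with a heavy tail, like real
  scaffold coverage.
- **Environmental database**: cultured references mutated to U(88, 97)%
  identity, standing in for an uncultured-clone database in the chimera
  screen.
- **Taxonomy strings** are synthetic 7-rank labels; query taxonomies are
  truncated at the rank corresponding to their novelty bin (novel-phylum
  queries keep only domain and phylum), which is what drives the
  "phylum_unclassified" groups in rank-abundance output.

What passing tests show: the pipeline's arithmetic, thresholds, and
recovery behavior are correct when divergence is substitution-only and
references are unrelated. What they do not show: robustness to indels and
rate heterogeneity (an optional indel rate exists but is outside the
standard conditions), to closely related reference sets (where top-hit
ambiguity is real), to primer amplification bias, or to chimeras of
closely related parents, which no coverage rule can catch. The generator
is a stand-in: the upstream study is observational and prescribes no
generative model.

## Problem sizes and determinism

Standard study conditions used by the test suite and the acceptance
script: a 16-reference database (12 bacteria, 4 archaea, 1,000 bp), a
300-query clean community for composition recovery, and an 800-query
community with 60 chimeras (7.5%) and 200 fragments (25%) for QC rates.
All randomness flows through a single integer seed per dataset
(`numpy.random.default_rng`); identical (spec, references, seed) triples
produce byte-identical outputs, and pipeline reruns with an identical
config reproduce identical checksums, recorded in each run's manifest.

## Known limitations

- Identity is measured against a *single* top hit; merging multiple HSPs
  or consulting secondary hits is out of scope.
- The census propagates no uncertainty from the literature cell totals.
- The CLI's `simulate` exposes the common generator knobs, not every
  field of `CommunitySpec`; use the library for full control.
- With very short references (<200 bp) the k-mer prefilter can miss
  genuinely alignable pairs; the no-hit semantics are defined in terms of
  shared k-mers, by design.
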