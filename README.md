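# microcensus

**How much of Earth's microbiome has never been cultured — and how novel is it?**

`microcensus` is a Python library (with a thin CLI) for censusing
*phylogenetic novelty* in environmental 16S rRNA gene data. Most microbial
diversity known from sequencing has no cultured representative; this package
implements the full analysis chain that turns raw 16S sequences into a
global estimate of how many microbial cells belong to uncultured taxa, and
how deep that novelty runs. It is aimed at microbial ecologists and
bioinformaticians who want the census arithmetic, the filtering rules and
the novelty binning as reusable, tested components rather than a one-off
analysis script.

## The method

For each query 16S sequence the pipeline finds the **single most similar
cultured isolate** (an affine-gap Smith–Waterman top-hit search with a
shared-*k*-mer prefilter; match +2, mismatch −3, gap `5 + 2k`). The percent
identity of that top hit places the query on a three-level novelty ladder:

| bin | identity *p* to nearest cultured relative | interpretation |
|---|---|---|
| cultured species-to-genus | *p* > 96.6 | member of a cultured genus |
| uncultured genus-to-class | 86 ≤ *p* ≤ 96.6 | novel genus, family, order or class |
| uncultured phylum+ | *p* < 86 | novel phylum or deeper |

The cutoffs are the upper 95% confidence bounds of the median within-rank
16S identity for genus and phylum. Before binning, sequences pass retention
rules: minimum lengths (>900 bp archaeal / >1,200 bp bacterial amplicons,
>900 bp assembly-derived genes), removal of no-hit queries, removal of top
hits spanning <300 bp of the query (partial hits to conserved regions), a
chimera screen (alignment spanning <90% of the query against **both** the
cultured and an environmental database), and removal of chloroplast,
mitochondrial and eukaryotic sequences.

Per environment *e*, the fraction of sequences in bin *b* is computed in
two weightings: plain counts, and scaffold-read-depth weighted,

&nbsp;&nbsp;&nbsp;&nbsp;*f<sub>m</sub>(b)* = Σ depth(i ∈ b) / Σ depth(i),&nbsp;&nbsp;
*f<sub>e</sub>(b)* = mean over metagenomes *m* of *f<sub>m</sub>(b)*,

i.e. a mean of fractions, not a pooled count — every metagenome gets equal
weight. Multiplying *f<sub>e</sub>* by literature estimates of total
microbial cells per biome *N<sub>e</sub>* (units of 10²⁶ cells) and summing
over environments gives the global census, under the conservative
simplification of a single 16S copy per genome (an optional mode applies
per-domain mean copy numbers, 3.8 for bacteria and 1.8 for archaea).

Because the real inputs are external databases, the package ships a
**synthetic-community generator** with exact truth labels (controlled
divergence, chimeric splices, short-fragment artifacts, log-normal scaffold
depths) so that every stage — and the pipeline end to end — is testable
offline.

## Worked example

```python
import microcensus as mc

census = mc.summarize_global(mc.load_census_fixture("metagenome"))
print(census.headline)
```

```
{'uncultured_pct': 81, 'uncultured_cells': 7.3e+29,
 'uncultured_phyla_pct': 25, 'uncultured_phyla_cells': 2.2e+29,
 'cultured_pct': 19, 'genera_to_classes_pct': 56}
```

Reading: of ~9×10²⁹ microbial cells in the seven censused biomes, **81%
(7.3×10²⁹ cells) belong to uncultured genera or higher taxa** and 25%
(2.2×10²⁹) to uncultured phyla; only 19% are from cultured species-to-genus
relatives. The metatranscriptome-based table (`"metatranscriptome"`),
which reflects ribosome-bearing, putatively active cells, raises the
uncultured share to 98% (5.9×10²⁹ cells) with uncultured phyla at 69%
(4.2×10²⁹).

A full synthetic run (see `examples/`): simulate a community with planted
composition 0.2/0.3/0.5 across the three bins, search, QC, bin and
aggregate — the recovered count-mode fractions are 0.200/0.300/0.500
(max error 0.000 at the default conditions), injected chimeras are flagged
at 100% with zero false positives, and >99% of short-fragment artifacts
are removed.

The `examples/` scripts each exercise one capability (simulation, search
and binning, QC, environment profiles, global census, rank abundance) and
print what the numbers mean. The same stages are available as a CLI:

```sh
microcensus simulate --outdir work --n-seqs 100 --seed 7
microcensus search --queries work/queries.fasta --refs work/cultured.fasta --out work/hits.tsv
microcensus census --fixtures metagenome
microcensus run --config config.yaml     # whole pipeline + manifest
```

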