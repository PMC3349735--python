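# tfbindmode

Binding-mode analysis for transcription-factor ChIP peak regions.

Members of large transcription-factor families (the ETS family alone has 28
human members) share nearly identical DNA-binding domains, so a genomic site
bound by one factor can often be occupied by its relatives. `tfbindmode`
implements the analysis that separates a focal factor's confident binding
regions into two classes — **redundantly bound** regions, which overlap the
binding of a second family member (e.g. ELK1 peaks overlapped by GABPA peaks),
and **uniquely bound** regions, which do not — and then asks whether the two
classes differ in sequence content, genomic geometry, regulatory outcome and
gene function. It is written for computational biologists working with ChIP
peak sets and a matched knockdown-by-stimulus expression experiment.

## What it computes

**Confidence calling.** Given two replicate peak sets (narrowPeak), the
high-confidence set is the replicate-2 regions (FDR < 10%) that overlap a
replicate-1 region; replicate-2-only regions form the low-confidence set.

**Binding-mode classification.** A high-confidence region is *redundant* iff
it shares ≥ 1 bp with a comparator-factor region, else *unique*. Each region
is assigned to the gene with the nearest TSS (by peak summit), giving the
per-gene binding-mode table.

**Motif content.** Degenerate-word scanning over IUPAC strings on both
strands, with palindromic matches collapsed. For an octamer consensus such as
the strong ETS word `CCGGAAGT` (or the relaxed variant `CAGGATGT`), sites are
counted as exact matches to its three hexamer derivatives
(`CCGGAA`, `CGGAAG`, `GGAAGT`), selected greedily left-to-right so counted
footprints never overlap; the reversed word serves as background. A composite
ETS–SRF *module* is an ETS site and an SRF CArG box (`CCWWWWWWGG`) whose
centres both lie within 100 bp of the peak summit and less than 50 bp apart.

**Expression response.** Probeset signals (log10) for the 2×2
control/knockdown × 0/30-min stimulus design are collapsed to one probeset
per gene (background filter, opposite-direction exclusion, largest-change
selection), tested per contrast with the two-factor batch-paired model
(Benjamini–Hochberg adjusted), z-transformed across the four condition means
(`z_c = (x_c − x̄)/s`, sample s), and clustered by k-means with k = 8, the
clusters display-ordered by hierarchical clustering of their means.

**Association statistics.** Pearson chi-square (df = 1, no continuity
correction) or Fisher's exact test for 2×2 tables; a Monte-Carlo gene-list
overlap z-score, `z = (observed − mean)/sd` over 10,000 random same-size
background lists; a per-chromosome permutation test for region-set overlap;
and hypergeometric gene-set enrichment over GMT files.

**Synthetic data.** Because the original ChIP-seq/microarray data are not
bundled, `tfbindmode.synthgen` generates a fully self-contained dataset —
genome, replicate and comparator peak sets, planted motif words, TSS table,
probeset expression matrix and gene sets — whose planted structure (class
sizes, proximal fractions, site-count modes, SRF/AP1/module rates, eight
response archetypes coupled to binding mode) matches the statistical shape
the analysis assumes, together with ground-truth labels for every region and
gene. Every pipeline stage is tested by parameter recovery against this truth.

## Worked example

```sh
tfbindmode run-all --seed 1 --out-dir out/
```

or equivalently from Python:

```python
from tfbindmode.pipeline import PipelineConfig, run_all
report = run_all(PipelineConfig(seed=1))
```

On the default synthetic configuration (303 unique / 226 redundant planted
regions before replicate dropout and FDR filtering) this prints a report
containing, at seed 1:

```
high-confidence regions: 449
unique: 254  redundant: 195 (43.4% comparator overlap)
within 2 kb of TSS: redundant 96.9%, unique 25.6%
modal strong-hexamer sites/region: redundant 3, unique 1
SRF CArG rate: unique 60.6%, redundant 25.6% (chi-square p = 1.58e-13)
ETS-SRF modules: unique 31.9%, redundant 9.2% (p = 9.44e-09)
bound vs knockdown-regulated gene overlap: 217 genes, z = 9.89
direction-by-mode (30 min): up 7U/58R, down 154U/22R, p = 3.03e-29
clustering ARI vs planted archetypes: 0.75
```

Reading: classification recovered every planted label (43.4% of confident
regions overlap the comparator); redundant regions are promoter-proximal and
carry multiple strong ETS words while unique regions are distal, carry one
(often variant) word, and are enriched for SRF CArG boxes and composite
ETS–SRF modules; knockdown-regulated genes overlap bound genes far beyond
chance; and uniquely bound genes are overwhelmingly down-regulated by the
knockdown while redundantly bound genes go up — the signature of activation
at unique sites and competitive/repressive binding at redundant ones.

Individual stages are available as subcommands (`simulate`, `confidence`,
`classify`, `motifs`, `express`, `associate`) operating on standard formats
(narrowPeak, FASTA, TSV, GMT).

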