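# Methods

## The state model

Dot1 deposits H3K79 methylation distributively: one methyl group per
productive encounter, no processive completion of higher states. We model
the number of productive events at a site as Poisson with mean λ ("dose",
dimensionless: expected events per H3K79 site), truncated at me3 because no
higher state exists. This is the minimal kinetic model that produces the
observed wave phenomenology — me1 peaking at λ = 1, me2 at λ = 2, me0
decaying and me3 accumulating monotonically — and we treat it as a modeling
choice, not an established rate law. It assumes a homogeneous site
population per gene (one λ per gene window), no demethylation, and no
state-dependent catalysis. Whether mammalian DOT1L is distributive is not
established; low-methylation regimes correspond to small λ under this model
but we make no mechanistic claim there.

Dose inversion uses λ̂ = −ln f₀ by default: f₀ is untouched by the me3
truncation, so this is exact under the model, and it degrades gracefully on
noisy input. An alternative bounded least-squares fit over all four states
(`method="lsq"`, search on [0, 20], tolerance 1e-12 on the dose) is more
robust when f₀ is small or noisy. f₀ = 0 is reported as "dose above
identifiable range" rather than returning infinity.

The me3/me1 activity ratio is f₃/f₁; f₁ = 0 with f₃ > 0 returns `inf`
(saturation) and f₁ = f₃ = 0 returns `nan` (undefined — the caller
decides). Bulk state tables are simple per-row normalizations to 100%,
mirroring what relative mass-spectrometry quantification reports.

## The synthetic genome

`SimulationConfig` defaults define the study conditions: 200 genes of
1.5 kb on 4 × 520 kb chromosomes (interior gene pitch 10 kb, so ~15% of the
genome is genic), 10% planted Rpd3 targets, 10% planted subtelomeric genes,
4-fold target dose/transcription/H2Bub gain, 0.25× subtelomeric dose loss,
~30× genome-mean coverage, 150-bp read extension, two replicates per
mark/genotype.

Per-gene wild-type doses are lognormal (log-mean ln 2, log-sd 0.7, clipped
to [0.4, 8]). The median of 2 places most genes past the me1 wave peak,
which is what makes me1 and me3 anti-correlate across the genome, as
observed in real data; the lower clip at 0.4 keeps the population inside
the regime where the measured me3/me1 ratio is monotone in λ (below ~0.4
the assay-background floor on me3 makes the measured ratio weakly
non-monotone). Planted classes draw from restricted log-uniform ranges
chosen analytically from the truncated-Poisson saturation ceiling, before
any end-to-end runs, so that the planted direction is measurable at the
default depth:

* targets: λ_wt ∈ [0.5, 1.5] — repressed, sub-saturation genes; a 4-fold
  gain then moves f₃ several-fold. Genes already at λ ≳ 2 cannot show a
  large me3 gain because f₃ saturates at 1, so highly methylated "targets"
  would be undetectable in principle, not merely at this depth.
* subtelomeric genes: λ_wt ∈ [1, 3] — enough wild-type methylation that a
  4-fold loss is visible above the background floor.

Transcription rate and H2Bub level are set equal to λ in arbitrary units
(trans-histone coupling: H2Bub tracks transcription and stimulates
methylation); targets scale all three 4-fold in the mutant, subtelomeric
genes scale them down 4-fold. Intergenic space carries a uniform background
dose of 0.3, so me1 (f₁(0.3) ≈ 0.22) is pervasive while me3
(f₃(0.3) ≈ 0.004) is effectively genic-only.

### Measurement model

Expected per-base signal for each mark is occupancy × state fraction (me1,
me3), occupancy (H3, H2B), or occupancy × H2Bub level; occupancy is flat at
1 by default. Two transforms mimic how real ChIP-seq measures this signal:

* **Nonspecific background**: each mark's measured signal is specific +
  β × (genome-mean specific), with β = 1.4 — roughly 40% informative reads,
  a realistic IP efficiency. This floors normalized coverage at
  β/(1+β) ≈ 0.58, which is what lets the 0.5-coverage gene filter behave
  as it does on real data (trimming only a few percent of genes) instead of
  deleting every low-methylation gene.
* **Library-size equalization**: each track is sampled to the same
  genome-mean coverage (the read budget is fixed by sequencing, not by
  the epitope's absolute abundance).

Setting `nonspecific_background=0, equalize_depth=False` gives the pure
proportional-signal model; the tests of signal-level properties (e.g.
window me3/me1 ratio → f₃/f₁) use that mode.

Reads are Poisson per-base 5′ start counts (rate = signal × depth / 150,
split evenly between strands) extended 150 bp in the strand direction —
read extension, not sequencer simulation. Replicates share expectations and
differ only in noise streams; all streams derive from the single config
seed via seed sequences keyed by (genotype, mark, replicate).

### What the generator does not emulate

Fragment-length variation, GC/mappability bias, nucleosome positioning fine
structure, antisense transcription, inter-gene occupancy differences, and
chromatin-state autocorrelation beyond gene bodies. Consequently H3/H2B
tracks are structureless: their replicate pairs fall below the r ≥ 0.8
merge threshold (there is no shared structure to correlate), and the
pipeline's documented fallback — keep replicate 1, warn — applies; the same
happens to me1, whose genome-wide contrast is weak by design. Passing tests
therefore demonstrate recovery of planted dose/transcription effects under
Poisson counting noise with realistic background and normalization, not
robustness to the full noise anatomy of real ChIP-seq.

## Coverage operations

Coordinates are 0-based half-open throughout; bedGraph I/O follows the
standard. The TSS of a minus-strand gene is `end − 1`; TSS windows are read
5′→3′ along the gene, so column 0 is always 500 bp upstream. Window
positions beyond a chromosome end are NaN and excluded from means —
zero-filling would bias exactly the subtelomeric genes the analysis cares
about. A plus-strand read at p covers [p, p+150); a minus-strand read
recorded by its exclusive end p covers [p−150, p). Out-of-bounds reads are
skipped and counted, not fatal. Binning takes the mean per bin, with a
trailing partial bin averaged over its actual width. RPGC multiplies by
genome_size/(total_reads × read_length); reads-per-million is also
available; the units tag on a track blocks double normalization. Merged
replicates are read-count-weighted means of coverage, and the merged track's
nominal read total is the weighted mean of the replicate totals (the value
that makes its RPGC scale correct).

## Per-gene metrics

Window statistics use the first 500 bp of the gene (ratios, filter) and the
full −500..+1000 window (zero-coverage clause). The filter drops a gene if,
in any required mark/genotype matrix, the full-window mean is exactly 0 or
the first-500-bp mean is below 0.5; "required" defaults to me1, me3 and H3
in both genotypes. A strict per-base variant (any zero base fails) exists
behind a flag but is not the default — at realistic depth it would discard
most of the genome. All ratios are pseudocounted, (num+ε)/(den+ε) with
ε = 0.1 in normalized-coverage units; a warning is emitted when doubling ε
flips the sign of the log₂ change for more than 5% of genes. The ranking
key is log₂ of the H3-normalized me3 statistic, mutant over wild type.

The Epi-ID score is log₂((me3/me1)_mutant / (me3/me1)_WT), 0 at wild-type
level. Growth correction is the residual of an ordinary least-squares
regression of the raw score on a growth covariate across the mutant
collection — a deliberately simple stand-in for the original screen's
correction, labeled as such; below 3 mutants it falls back to the raw score.

## Rank analysis

Ranking is descending by log₂ change with deterministic gene-id
tie-breaking. Groups I–IV are cut at (−0.5, 0.5, 1.5) log₂ units — free
parameters exposed in the config, since the original partition was drawn
graphically.

LOESS over rank uses tricube-weighted local linear fits (span 0.3 of the
genes); the 95% band is a percentile interval over 200 seeded bootstrap
resamples of genes, clipped to bracket the point fit (a raw percentile
band can exclude it at sharp features). Spans below 4 points per
neighborhood are rejected.

The barcode enrichment statistic is the rank-sum of the gene set. Its null
— all C(n, k) placements equally likely — is computed exactly by a
subset-sum dynamic program when C(n, k) ≤ 1e5 (equivalent to full
enumeration, and tested against it), otherwise by the Mann–Whitney normal
approximation with continuity correction. `top` asks whether the set
concentrates at small ranks, `bottom` at large; `two-sided` doubles the
smaller tail. Over-representation is the hypergeometric upper tail
P(X ≥ k) with fold = (k/n)/(K/N). Subtelomere annotation takes the minimum
distance of a gene's two ends to the nearer end of its chromosome;
< 30 kb flags the gene.

## Pipeline, determinism, problem sizes

The `run` pipeline executes simulate → extend/normalize → merge → TSS
matrices (10-bp bins) → metrics/filter → rank/groups → LOESS → enrichment
of the planted sets (plus any user-supplied gene lists) → bulk fractions,
writing every table with a provenance header (version, seed, config hash).
Identical config + seed reproduces every output byte-for-byte; the
acceptance script verifies this by running the pipeline twice.

Problem sizes — 200 genes, 2.1 Mb genome, 30× coverage, two replicates,
200 bootstrap replicates, 1e6 Monte-Carlo sites — are the package's default
desk-scale study conditions; a full pipeline run takes ~10 s on one CPU,
and every threshold (filter 0.5, merge r 0.8, ε 0.1, cutpoints, spans,
folds) is a config parameter.

## Known limitations

* The truncated-Poisson model ignores nucleosome turnover and
  demethylation-free dilution dynamics; λ is an effective, not physical,
  rate.
* The me3/me1 ratio loses monotonicity in λ below the background floor
  (λ ≲ 0.4 under default measurement settings) and saturates above λ ≈ 6.
* The exact rank-sum path is O(n·k·Σranks) and is deliberately limited to
  small universes; large-universe p-values are approximate (continuity
  corrected) and floored at the smallest positive double.
* The growth correction is a linear residual, not the original screen's
  procedure.
* Real-data ingestion is limited to bedGraph/BED6/TSV; BAM/bigWig inputs
  must be converted upstream.
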