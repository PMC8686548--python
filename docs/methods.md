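# Methods

## Model

The package prices the two sides of an endosymbiotic gene transfer event in
ATP per cell doubling and takes the difference:

* **DNA side.** One double-stranded copy of a gene costs
  `A_DNA = length × (gc × 40.14 + (1 − gc) × 40.55)` ATP. The cell pays
  this once per genome copy, so moving the gene from an organellar genome
  at copy number `C_end` to a nuclear genome at `C_nuc` saves
  `ΔD = A_DNA (C_end − C_nuc)` per doubling. Published estimates of the
  per-nucleotide cost vary by ~20%; because this constant always multiplies
  a copy-number difference spanning five orders of magnitude, the choice
  within that range is immaterial to the conclusions.
* **Protein side.** After transfer the protein must be imported into the
  organelle at `C_import` ATP per residue, for all `N_p` copies required
  per doubling: `ΔP = L_prot × C_import × N_p`. Production cost is assumed
  identical in the organelle and the cytosol and cancels, so the only
  protein-side term is import. `N_p` is continuous (abundances are
  ratio-scale estimates, not counts):
  `N_p = ppm/10⁶ × organellar_fraction × total_proteins × turnover`.

`ΔE_EGT = ΔD − ΔP`; positive favours nuclear encoding. Genes at exactly
zero are classed *neutral* and reported separately from both favourable
classes; retained-gene counts use strict `ΔE_EGT < 0`. The copy number `N*`
at which the two sides balance,
`N* = A_DNA (C_end − C_nuc) / (L_prot C_import)`, is exposed as the
retention threshold.

Whole-cell context comes from volume-scaled growth and maintenance costs,
`C_r = 26.92 V^0.97` (10⁹ ATP) and `C_m = 0.39 V^0.88` (10⁹ ATP h⁻¹), with
replication energy `E_R = C_r + t·C_m` over a doubling time of `t` hours.
The fraction of `E_R` saved by one transfer is used directly as the
selection coefficient `s`. Organelle-internal ATP turnover beyond the
volume-scaled maintenance term is not modelled.

## Parameters and defaults

| parameter | default | rationale |
| --- | --- | --- |
| ATP per A:T / G:C bp | 40.55 / 40.14 | complete biosynthesis cost of a base pair |
| amino-acid ATP costs | aerobic opportunity-cost set (11.7–74.3 ATP/residue) | the standard cost table of cellular-economics work; configurable wholesale through `CostTable` |
| histones | yeast H2A/H2B/H3/H4 lengths × mean residue cost | the octamer composition is fixed (2 of each per 180 bp) but the species source of histone costs is a free choice; full sequences may be supplied for exact composition-weighted costs |
| nucleosome spacing | 180 bp (147 wrap + 33 spacer), `ceil(length/180)` octamers | ceiling covers partial windows so all nuclear DNA is packaged |
| `C_nuc` | 2 | diploid host |
| `C_end` | 1–10,000 swept | single-copy start of an endosymbiosis up to plant-chloroplast-like polyploidy |
| `C_import` | 0.05–5 ATP/residue swept (50 as an extreme) | span of measured import-cost estimates; machinery biosynthesis overhead (~0.2–0.7 ATP/residue when amortised, see `machinery_overhead_per_residue`) falls inside this range |
| host protein count | 10⁷–10⁹ | small yeast-like to metazoan/plant-like cells |
| organellar fraction | 0.02–0.5 | mitochondrial (~2–5%) to chloroplast-rich (~50%) allocations |
| turnover | 1 (up to 50 swept) | most proteins turn over by replicative dilution; 5–50 models long-lived or non-dividing cells |
| doubling time | 24 h | unicellular ancestral host assumption |
| protein density | 10⁶ proteins/µm³ | converts protein count to volume for the budget; calibrated on a yeast cell of ~4 × 10⁷ proteins in ~40 µm³ — the budget model is volume-based and this conversion is the package's own bridging choice, exposed as a `CellModel` field |

With these defaults a 10⁷-protein host has `E_R ≈ 3.2 × 10¹¹` ATP, and the
median transfer-favourable gene of a 1500-gene endosymbiont carries
`s ~ 10⁻⁵` at 100 genome copies and `s ~ 10⁻⁴` at 1000 — the scales the
analysis is designed to resolve.

## Synthetic data

`GenomeSpec` draws gene lengths log-normal (default mean ≈ 950 bp, the
average CDS length of the alphaproteobacterial and cyanobacterial model
genomes; log-sd 0.45), rounds them to codon-complete multiples of 3 with a
90-bp floor, draws GC ~ N(0.40, 0.05) truncated to [0, 1], and draws
abundances log-normal (log-sd 1.5) normalised to exactly 10⁶ ppm. The
log-sd of 1.5 gives a 99th-percentile/median ratio above 30, the kind of
heavy tail measured proteomes show; the true fitted abundance distributions
of the model proteomes are not published, so these are realistic rather
than reproduced values, chosen once. Protein length is `length/3 − 1` (the
stop codon encodes no residue). `CohortSpec` produces L/T/R-labelled
tables whose retained group is shifted up by a configurable amount in log10
ppm.

What the generator does **not** emulate: codon usage and real sequence
composition (fixture FASTA sequences are random bases at the target GC),
operonic structure, correlations between abundance and gene length or
function, and measurement noise structure of real abundance data. Passing
tests therefore demonstrate the accounting, its monotonicities and its
statistical calibration — not organism-specific gene-by-gene predictions,
which require real genome + abundance inputs via the FASTA/GFF3/PAXdb
readers.

## Wright-Fisher simulator

Haploid by default: a transfer allele starts at frequency `1/N`, each
generation is a deterministic selection step `p* = p(1+s)/(1+ps)` followed
by exact binomial resampling of N copies (no Gaussian/Poisson shortcut —
exactness at small N matters more than speed at desk scale). The paper-scale
population of 10⁷ is supported, but tests and examples use N ≤ 10⁴ with
N·s held at the relevant magnitudes; a `diploid` flag switches to 2N copies
and `p0 = 1/2N`. The generation cap defaults to 20 N (several times the
neutral conditional fixation time); results flag runs where more than half
the replicates were still segregating at the cap. Calibration is checked
against the neutral `p_fix = 1/N` and Kimura's diffusion approximation at
`Ns ∈ {1, 10}`.

## Cohort statistics

Abundances are log10-transformed by default before the one-way ANOVA —
ppm values span orders of magnitude and residual normality is untenable on
the raw scale — with a raw-scale mode available since the transform choice
is analyst-dependent. Zeros under the log transform are dropped with a
recorded count (a pseudo-count mode substituting half the smallest positive
value is provided). Pairwise comparisons use Tukey's HSD at α = 0.05, and
group letters come from the insert-and-absorb compact-letter-display
algorithm, so groups share a letter exactly when their adjusted p ≥ α. The
omnibus ANOVA can be run without the (comparatively expensive) pairwise
step via `pairwise=False`.

## Numerical and design choices

* The headline "bp saved per cell" metric is `length × C_end`, deliberately
  ignoring the 2 nuclear copies gained — it reproduces the standard
  back-of-envelope values exactly (0.04% off the full difference at
  `C_end = 5000`); the exact `C_end − C_nuc` form is used everywhere ATP
  is accounted.
* Grid sweeps are fully deterministic, keyed by explicit parameter tuples;
  per-gene detail is optional to bound memory on large grids; class counts
  always sum to genome size.
* Unknown GC falls back to the mean pair cost (40.345 ATP/bp).
* Selection spectra sort by decreasing |s| with gene-id tiebreak for stable
  output.
* Abundance joins default to dropping unmatched genes (only measured
  proteins inform per-gene results); `zero_fill` keeps them with zero
  import cost, which makes them maximally transfer-favourable.
* GFF3 coordinates are 1-based inclusive externally, 0-based half-open
  internally; minus-strand CDS are reverse-complemented before GC
  computation (GC is strand-symmetric, so this affects sequence extraction
  only).
* CDS lengths not divisible by 3 are kept with a warning and floor-division
  protein length.

## Scope and limitations

Transcription/translation machinery, RNA, chaperone and organellar
DNA-binding-protein costs are out of scope (their inclusion would only
widen the organellar/nuclear cost gap). Organellar targeting prediction and
the orthology inference that assigns real genes to lost/transferred/
retained cohorts are consumed as inputs, not computed. Test and example
problem sizes (1500-gene genomes, 3⁵ grids, N ≤ 10⁴ Wright-Fisher runs with
≤ 10⁵ replicates) are the package's chosen desk scale; all operations
accept larger inputs.
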