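# Methods

This note documents the models, estimators and design choices behind
`nemamito`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, with which
defaults, and what the synthetic benchmarks do and do not demonstrate.

## Genome ingestion and coding-sequence extraction

GenBank flat files are parsed with Biopython. Internally all coordinates
are 0-based half-open on the stored strand; GenBank's 1-based inclusive
convention (including `join(a..L,1..b)` origin-spanning locations on
circular genomes) is converted once at the parsing boundary. Gene names
are reconciled onto the 12 shared PCG names through a shipped,
user-extensible synonym table (`data/gene_synonyms.tsv`); public
annotations are heterogeneous (COI/CO1/cox1, ND4L/nad4l, cob/cytb, …) and
no authoritative reconciliation standard exists, so the table is a curated
best effort and unmatched names map to `OTHER` rather than guessing.

Extraction reverse-complements minus-strand genes onto the coding strand,
drops the `codon_start − 1` leading nucleotides, and truncates any
trailing partial codon. Incomplete stop codons completed by
polyadenylation are *not* padded: padding invents data, truncation loses
at most two nucleotides of a codon that carries no usable information for
any downstream statistic. Internal stops are detected under the
invertebrate mitochondrial code (NCBI table 5: AGA/AGG = Ser, ATA = Met,
TGA = Trp, stops TAA/TAG only) and flagged, not fatal.

Circular genomes are rotated to the conventional COX1-first orientation
(reverse-complementing the whole genome first if COX1 is annotated on the
minus strand). Whole-genome skews are computed **after** this orientation;
orientation flips the sign of a strand-asymmetric metric, so fixing the
convention and recording it in the run manifest is what makes skews
comparable across genomes.

## Composition metrics

GC skew = (G−C)/(G+C), AT skew = (A−T)/(A+T), %GC = 100·(G+C)/(A+C+G+T).
Only unambiguous A/C/G/T count; IUPAC ambiguity codes and gaps are
excluded from numerator and denominator alike, so an N-run cannot bias a
skew. A zero denominator yields a typed undefined value that group
summaries exclude *and count* — silent NaN propagation would hide data
loss. Codon-position skews are the skew of every third nucleotide of a
frame-trimmed coding sequence; the three position subsequences partition
the sequence exactly.

## Substitution rates

Large comparative studies in this domain typically estimate pairwise rates
with a maximum-likelihood codon model; this package deliberately implements
the transparent counting alternative (Nei–Gojobori 1986 family) as its
desk-scale core:

- **Sites.** For each sense codon, each position contributes the fraction
  of its three single-nucleotide changes that are synonymous, with
  stop-creating changes excluded from that position's denominator. Site
  counts therefore satisfy s + n = 3 per codon exactly, and S + N =
  3 × (compared codons) for every pair.
- **Differences.** Codon pairs are classified along all minimal
  single-step paths; paths through a stop codon are discarded and the
  survivors weighted equally (the canonical default; no data exist to
  justify unequal weights). If *every* minimal path crosses a stop — a
  degenerate case — classification proceeds over all paths and the result
  is flagged.
- **Correction.** pS = Sd/S and pN = Nd/N are corrected with the
  Jukes–Cantor map d = −(3/4)·ln(1 − (4/3)p), which is within 10⁻⁴ of p
  below p = 0.01 and undefined at p ≥ 3/4; such pairs are reported
  `saturated_dS`/`saturated_dN` rather than extrapolated.
- **Masking.** Codons containing a gap, ambiguity or stop in either taxon
  are masked pairwise, preserving the rest of the gene rather than
  dropping whole sequences; pairs with fewer than `min_codons = 30`
  comparable codons are `insufficient_sites`. This threshold makes the
  "missing rate cell" behavior of ML engines explicit and tunable.
- **Aggregation.** Each ingroup sequence is compared against the
  five-member outgroup panel (two tardigrades, three arthropods); dN and
  dS are averaged over the status-ok pairs only, with the count recorded,
  and ω is the **ratio of the averaged rates**, not the average of
  per-pair ratios — robust to a near-zero dS in any single pair.

**Known estimator limitation.** Equal-weight site counting assumes an
unbiased mutation process. Under transition/transversion bias (κ > 1) the
synonymous-site flow is underestimated and ω is biased downward (on the
order of 20% at κ = 2 in this package's own simulations); this is the
textbook NG86 property, not an implementation artifact. Parameter-recovery
benchmarks therefore evolve sequences at κ = 1, the estimator's matched
mutation model, while the dataset generator defaults to a realistic κ = 2.
Absolute rate magnitudes from a counting estimator are also not comparable
to ML-extrapolated rates on deeply saturated comparisons; contrasts and
orderings across genes, clades and traits are the comparable surface, and
the run manifest records the estimator choice.

## Saturation testing

A fully saturated alignment column is statistically indistinguishable from
an iid multinomial draw from the pooled base frequencies. The index is the
mean per-column Shannon entropy of resolved sites divided by the entropy of
the pooled frequencies. Normalizing by pooled-frequency entropy rather
than log₂4 matters in genomes this AT-rich: a uniform-alphabet ceiling
would make even full saturation look "unsaturated". The observed index is
compared against a Monte-Carlo null of `n_reps = 500` same-shape
alignments drawn from the pooled frequencies; the verdict bands on
z = (obs − null mean)/null sd are `not_saturated` at z ≤ −6,
`saturated` at z ≥ −2, `substantial` between (configurable). The classic
desktop tool for this analysis ships simulation-calibrated critical-value
tables keyed to tree-recovery performance; those tables are not derivable
from first principles, so this package substitutes the transparent
Monte-Carlo null and says so in its output. Minimum problem size: 4 taxa
and 20 resolved sites. Resolved-site masks are codon-granular — a codon
with any gap/ambiguity in a taxon is masked whole for that taxon — because
mixing resolved and unresolved positions within one codon corrupts
codon-level statistics.

## Trait association

Each metric is tested against categorical predictors with a tie-corrected
Kruskal–Wallis test (scipy), chosen for robustness to the strongly uneven
group sizes and non-normal metric distributions typical of this data.
"Blocking" is stratification: a separate test within each clade plus a
pooled test, which is the reading consistent with reporting clade-specific
statistics; a rank-aligned pooled alternative is intentionally not
implemented. Blocks whose predictor is constant (e.g. a clade that is
entirely animal-parasitic and amphimictic) are retained as skipped entries
with the reason. Effect size is ε² = H/(n−1) clipped to [0, 1]. FDR is
Benjamini–Hochberg within the family {one metric × all predictors × all
blocks}; "adjust everything" is ambiguous, so the family definition is
fixed and recorded in the output. Dunn post-hoc z-tests use the standard
rank formulation with the tie term T = Σ(t³−t)/(12(N−1)) and BH adjustment
across pairs; for two tie-free groups z² equals H. Groups smaller than 2
are dropped and logged. Degenerate all-tied data yield H = 0, p = 1.

## Synthetic-data generator

The generator is first-class, tested code, and its defaults are the study
conditions used throughout the test suite and the acceptance script:

- **Shape.** 20 species over four clades (Enoplea, Tylenchina,
  Rhabditina, Spirurina, round-robin), 12 PCGs with codon counts
  approximating the nematode genes (COX1 ≈ 520, NAD4L ≈ 80, …; ~10.2 kb
  coding), 22 tRNA + 2 rRNA placeholder features, and noncoding spacers
  targeting 30% of the genome with ±~20% per-species variation — genomes
  around 14–15 kb, matching the clade's typical sizes.
- **Composition.** Target 25% GC with per-position GC skews
  (0.25, −0.05, 0.40): AT-rich with a strong third-position G skew, the
  signature structure of these genomes. Codon frequencies are solved by
  fixed-point iteration so the *stop-conditioned* distribution hits the
  targets exactly in expectation (naive per-position sampling conditioned
  on stop-freedom would miss the pos-3 skew target by several points);
  infeasible targets raise an error reporting the nearest feasible point.
- **Divergence.** Per-codon Gillespie simulation: single-nucleotide
  proposals, κ-fold transition weighting (default κ = 2), stop proposals
  rejected, non-synonymous proposals accepted with probability ω, every
  accepted event logged. Ingroup lineages diverge from a shared per-gene
  root at an expected 5% of sites changed; the outgroup panel at 15%. The
  outgroup depth is chosen so that most — not all — ingroup–outgroup pairs
  stay inside a counting estimator's correction domain: synonymous
  divergence concentrates ~3–4× the nucleotide divergence, so deeper
  settings silently saturate the majority of rate cells, while some
  saturated cells are retained deliberately to exercise the missing-data
  path end to end.
- **Planted effects.** ω by feeding habit (0.05 animal parasites … 0.20
  predators/omnivores; outgroups 0.10), and third-position skew shifts for
  parasites (−0.35 animal, +0.12 plant) applied as synonymous
  third-position resampling (protein-preserving, logged as synonymous
  events). Spirurina is generated entirely animal-parasitic and
  amphimictic so that constant-predictor block skipping is exercised.
- **Not emulated.** Indels and alignment error (alignments are emitted
  gap-free; alignment is an upstream, out-of-scope stage), tRNA/rRNA
  sequence realism, genome rearrangement, composition-stationary
  evolution. On that last point: the substitution process is not
  stationary at the root composition, so planted skews decay measurably
  toward the process's equilibrium as lineages diverge (fastest at third
  positions); tests of target recovery on *emitted genomes* therefore
  carry wider tolerances than tests of the sampler itself. Passing tests
  demonstrate internal consistency of extraction, estimation and
  calibration under known truth — not that real annotation noise, indels
  or selection heterogeneity are handled.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; dataset builds and full
pipeline runs are byte-reproducible for a fixed configuration. The default
benchmark sizes are deliberately desk-scale: 20 species × 12 genes for
end-to-end runs; 10,000-codon pairs × 50 replicates for ω recovery;
1,000 null simulations for Kruskal–Wallis type-I calibration; 32 taxa ×
1,000 sites × 500 Monte-Carlo replicates for saturation calibration. A
full pipeline run completes in seconds; the complete test suite in around
a minute on one CPU.
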