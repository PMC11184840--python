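# nemamito

Comparative mitochondrial genomics for nematodes: a tested, reusable
pipeline for profiling mitogenome composition at codon-position resolution,
estimating outgroup-referenced substitution rates, quantifying mutational
saturation, and testing genome characteristics against life traits.

## Who this is for

Nematode mitochondrial genomes are small (roughly 12–26 kb), AT-rich
(GC content mostly 20–40%), circular, and carry 12 protein-coding genes
(PCGs: COX1–3, CYTB, NAD1–6, NAD4L, ATP6 — *atp8* is usually absent), 22
tRNAs and 2 rRNAs. They show some of the strongest coding-strand
compositional skews among metazoans, with clade- and trait-specific
patterns (parasitic lineages in particular). This package implements the
desk-scale analytical core for comparative studies of such genomes: given
annotated GenBank records, per-gene codon alignments and a life-trait
table, it produces the heatmap-ready tables (composition, skews, rates,
saturation) and association statistics that such a study reports.

## What it computes

- **Composition and skews.** For each genome, PCG, and codon position:
  lengths, %GC/%AT, GC skew = (G−C)/(G+C) and AT skew = (A−T)/(A+T) on the
  relevant strand (stored strand after COX1 orientation for genomes, coding
  strand for genes). Undefined skews (no G/C at all) propagate as typed
  missing values, never silent NaNs.
- **Substitution rates.** Pairwise dN and dS per gene under the
  invertebrate mitochondrial code (NCBI translation table 5; stops TAA/TAG
  only), via a Nei–Gojobori-type counting estimator: expected synonymous
  (S) and non-synonymous (N) site counts by single-nucleotide neighbor
  enumeration, differences classified along all minimal stop-free
  mutational paths with equal weights, and the Jukes–Cantor correction
  d = −(3/4)·ln(1 − (4/3)p). Each ingroup sequence's rates are averaged
  over a five-member outgroup panel (two tardigrades, three arthropods) and
  dN:dS (ω) is the ratio of the averaged rates. Saturated pairs
  (p ≥ 3/4) and short overlaps become recorded missing cells.
- **Saturation.** An entropy-based saturation index per gene, codon
  position and clade: mean per-site Shannon entropy of resolved columns,
  normalized by the pooled-base-frequency entropy, tested against a
  Monte-Carlo full-saturation null (iid multinomial columns) with a
  z-based verdict.
- **Trait association.** Tie-corrected Kruskal–Wallis tests of every
  metric against life traits (feeding habit, habitat, reproduction) and
  taxonomic ranks, stratified ("blocked") by clade as well as pooled, with
  ε² = H/(n−1) effect sizes, Benjamini–Hochberg FDR within per-metric
  families, and Dunn post-hoc comparisons.
- **Synthetic data.** A generator for complete annotated mitogenomes and
  codon alignments with known ground truth: composition targets solved
  exactly over the stop-free codon alphabet, codon-level Gillespie
  divergence at prescribed ω and κ with logged synonymous/non-synonymous
  events, planted trait effects, and a five-outgroup panel.

## Worked example

```python
from pathlib import Path
import pandas as pd
from nemamito.pipeline import RunConfig, run, simulate_dataset

simulate_dataset(11, "demo/data", n_species=20)   # synthetic study dataset
cfg = RunConfig(
    genomes_dir="demo/data/genomes",
    alignments_dir="demo/data/alignments",
    trait_table="demo/data/traits.tsv",
    newick="demo/data/tree.nwk",
    outdir="demo/out",
    seed=11,
)
out = run(cfg)

comp = pd.read_csv(out / "composition.tsv", sep="\t")
rates = pd.read_csv(out / "rates.tsv", sep="\t")
ok = rates[rates.status == "ok"]
print(f"genomes: {len(comp)}, mean length {comp.genome_length.mean():.0f} bp, "
      f"mean %GC {comp.genome_pct_gc.mean():.1f}")
print(f"rate cells: {len(rates)} ({(rates.status == 'missing').mean():.0%} missing), "
      f"mean dN:dS {ok.omega.mean():.3f}")
kw = pd.read_csv(out / "kw_tests.tsv", sep="\t")
top = kw[(kw.block == "all") & (kw.grouping == "feeding_habit")].nsmallest(3, "p_raw")
print(top[["metric", "H", "p_raw", "p_adj", "epsilon_sq"]].round(4).to_string(index=False))
```

prints

```
genomes: 20, mean length 15026 bp, mean %GC 25.8
rate cells: 240 (38% missing), mean dN:dS 0.074
     metric       H  p_raw  p_adj  epsilon_sq
       dNdS 16.4112 0.0058 0.0692      0.8637
pcg_gc_skew 16.2643 0.0061 0.0735      0.8560
         dS 16.0592 0.0067 0.0801      0.8452
```

The 20 synthetic genomes average ~15 kb at ~26% GC, matching the
generator's targets. 38% of the 240 species × gene rate cells are missing —
pairs against the deep outgroup panel whose synonymous divergence exceeds a
counting estimator's correction domain, the analogue of rate cells lost to
unresolved sites in maximum-likelihood engines. The mean dN:dS of 0.074
reflects the strongly purifying ω the simulator planted (0.05–0.20 by
feeding habit), and the trait battery ranks dN:dS and PCG GC skew as the
metrics most associated with feeding habit — exactly the effects the
generator planted (feeding-specific ω and third-position skew shifts for
parasites).

The same stages are available from the shell:

```bash
nemamito simulate --seed 11 --outdir demo/data
nemamito run-all --config config.yaml
```

where `config.yaml` holds the `RunConfig` keys above. Each run writes a
`manifest.json` with the full configuration, seed, thresholds and input
digests; reruns with the same seed are byte-identical.

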