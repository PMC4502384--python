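# cochip

Differential ChIP co-occupancy analysis of two DNA-binding factors.

Chromatin studies of paralogous co-repressors — for example the two
*Drosophila* retinoblastoma-family proteins, which co-occupy many promoters
yet each bind large private target sets — keep asking the same four
questions: which genes does each factor bind, which promoters are co-bound
versus bound by only one factor, which sequence motifs explain the binding
signal, and whether motif sites are *stronger* where both factors sit
together. `cochip` packages that analysis as a reusable, deterministic
pipeline for peak sets, coverage tracks, a gene annotation and a PWM
library, together with a truth-annotated synthetic data generator so every
stage can be validated end to end without external downloads.

## What it computes

- **Peak annotation.** Each peak (anchored at its summit, else the interval
  midpoint) is assigned to the gene with the nearest TSS; the signed,
  strand-aware distance classifies it as promoter (−1 kb … +100 bp), gene
  body or intergenic. A gene is *bound* when a peak anchor lies within
  500 bp of its TSS, and the two factors' calls partition the gene universe
  into `both / A_only / B_only / none`.
- **Peak-set overlap.** Two peak sets overlap where anchors are ≤ 100 bp
  apart or intervals intersect; significance comes from an upper-tail
  hypergeometric model on genome bins (validated against a permutation
  null).
- **Promoter enrichment.** For each gene, the maximum over sliding windows
  (default 50 bp) of mean coverage within the 500 bp upstream of the TSS.
- **Motif scanning.** Log₂-odds PWM scores with *exact* site p-values under
  an i.i.d. background, computed by dynamic-programming convolution of
  discretized per-position score distributions (MAST-style); sites are
  reported at p ≤ 5 × 10⁻⁴ and reduced to a non-overlapping set,
  strongest first.
- **Association screen.** Per motif, a promoter *occupancy score*
  `Σ_w 2^(s(w) − s_max)` (the relative-affinity sum over all windows, both
  strands) is correlated (Pearson) with each factor's enrichment across the
  gene universe. Correlations are categorized high (r > 0.19) / medium /
  negative, and between-factor differences as shared (< 0.04),
  intermediate, or differential (> 0.14).
- **Site-strength comparison.** Pooled −log₁₀ site p-values from co-bound
  vs. single-factor promoters are compared by a one-sided Mann-Whitney U
  test ("co-bound stronger", α = 0.05), with the opposite direction and a
  Benjamini–Hochberg column reported alongside.
- **Gene-set summaries.** Fractions of named gene sets bound by each
  factor, with hypergeometric enrichment p-values.

## Worked example

```python
from cochip import SyntheticSpec, generate_dataset, analyze, evaluate_recovery

spec = SyntheticSpec(seed=7, n_chroms=1, chrom_length=120_000, n_genes=60,
                     n_decoys=5)
ds = generate_dataset(spec)
res = analyze(ds.genome, ds.genes, ds.peaks["A"], ds.peaks["B"],
              ds.coverage["A"], ds.coverage["B"], ds.motifs)

print("co-binding classes:", res.cobinding.counts)
print(res.screen.head(3).to_string(index=False))
planted = ds.truth.planted_motif_id
s = res.strength_results[planted]
print(f"{planted}: {s.n_cobound} co-bound vs {s.n_single} single sites, "
      f"U={s.u_statistic:.0f}, one-sided p={s.p_cobound_greater:.2e}, "
      f"direction={s.direction}")
```

prints

```
co-binding classes: {'both': 23, 'A_only': 4, 'B_only': 15, 'none': 18}
 motif_id    r_A   r_B delta category_A category_B delta_category  undefined
motif_000  0.748 0.666 0.082       high       high   intermediate      False
motif_003  0.201 0.272 0.071       high       high   intermediate      False
motif_005 -0.032 0.112 0.144   negative     medium   differential      False
motif_000: 48 co-bound vs 20 single sites, U=746, one-sided p=4.00e-06, direction=co_bound
```

`motif_000` is the motif the generator actually planted: it tops the screen
with "high" correlations for both factors, and its sites in co-bound
promoters are significantly stronger than in single-factor promoters — the
planted differential (sampling temperature 0.5 vs 1.0). The recovery report
(`evaluate_recovery`) confirms the co-binding classes match the generator
truth exactly for this dataset.

The same analysis runs from the shell on files:

```sh
cochip simulate --seed 7 --outdir sim/
cochip run-all --config config.yaml        # paths + thresholds in YAML
```

Every output TSV carries a provenance header (tool version, config hash);
`manifest.json` lists all outputs with sha256 checksums, and a rerun with
identical inputs and configuration reproduces identical checksums.

## Layout

- `src/cochip/formats_io.py` — FASTA, BED, gene table/GFF3 subset, wiggle /
  bedGraph, MEME-minimal PWMs; coordinate conventions.
- `src/cochip/peak_annotation.py` — nearest-gene assignment, binding calls,
  co-binding classes, overlap statistics.
- `src/cochip/promoter_signal.py` — max-average promoter enrichment.
- `src/cochip/motif_engine.py` — PWM scanning, exact site p-values,
  non-overlapping sites, occupancy scores.
- `src/cochip/association_stats.py` — correlation screen, Mann-Whitney
  strength comparison, gene-set summaries.
- `src/cochip/synthetic_data.py` — truth-annotated generator and recovery
  evaluation.
- `src/cochip/pipeline.py`, `src/cochip/cli.py` — orchestration and the
  `cochip` command.

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
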