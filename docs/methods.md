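# Methods

## Scope and coordinate conventions

`cochip` analyses two factors' ChIP peak sets and coverage tracks against a
gene annotation and a PWM library. All internal coordinates are 0-based
half-open; 1-based conventions exist only at format boundaries (wiggle, the
gene-table `tss` column, GFF3). A gene's promoter window is the `upstream`
bases 5′ of the TSS (default 500, optionally extended downstream), oriented
by strand: windows of minus-strand genes are taken to the right of the TSS
and their sequence is reverse-complemented before motif work, so "upstream"
is always biologically upstream. Windows are truncated at chromosome
bounds; a window that truncates to nothing is a distinct "empty" signal,
not an error.

## Peak annotation and binding calls

A peak is represented by one anchor base: its summit when the peak file
provides one, else the interval midpoint (integer floor). The summit is the
best point estimate of the protein–DNA contact; the midpoint is the
fallback when no summit was called. Each peak is assigned to the gene
minimizing |anchor − TSS| on its chromosome, with ties broken by
lexicographic gene id for determinism. The signed distance is negative
upstream (strand-aware); a peak is labelled `promoter` when the distance
falls in [−1000, +100], else `gene_body` when the anchor lies inside the
gene span, else `intergenic`. Finer categories (5′UTR, exons, TTS) are
deliberately collapsed: nothing downstream consumes them.

The per-gene binding call is separate from annotation: a gene is bound by a
factor when some peak anchor lies within `binding_max_dist` (default
500 bp) of its TSS, symmetric and inclusive at the boundary. Two factors'
calls partition the universe into `both / A_only / B_only / none`; the
partition always sums to the universe size. A pipeline option
(`binding_rule: annotation_window`) instead derives calls from the
annotation window, since published per-gene summaries can be based on
either convention.

## Peak-set overlap significance

Two peaks overlap when their anchors are within `threshold` (default
100 bp) or their intervals intersect. For significance the genome is
divided into bins of width `2 * threshold`; the sets occupy the distinct
bins hit by their anchors, and the p-value is the upper-tail
hypergeometric probability of sharing at least the observed number of bins,
reported as log10. This bin model is this package's own null (the
published analyses used a tool whose null is not restated); it is validated
against a 1000-shuffle permutation null, which it tracks within a few
percent on log10 scale when bin collisions are rare. Two caveats are
inherent to the model: on very dense toy genomes (many anchors per bin) the
conditioning on distinct occupied bins departs from a position-shuffle null
by ~10–15%, and because binning has a fixed origin the log10 p is only
approximately invariant (±15%) under coordinate mirroring, while the
overlap *count* is exactly invariant.

## Promoter enrichment

The enrichment statistic is the maximum over all fully-contained sliding
windows of length `window_w` of the mean coverage inside the promoter
window; if the promoter is shorter than `window_w` the mean over the whole
interval is used (no partial windows at edges otherwise). The statistic is
linear in the track, monotone under pointwise increase, and reduces to the
interval max at `window_w = 1` and the interval mean at the interval
length. `window_w` defaults to 50 bp — an order-of-magnitude match to
ChIP-exo footprints; no published value constrains it, so it is surfaced in
every output header. Missing coverage (absent chromosomes, bases beyond the
track) counts as 0, matching peak callers' sparse wiggle output, and genes
sharing a bidirectional promoter each receive the full signal of the shared
bases.

## Motif model

PWMs carry probabilities as parsed (rows renormalized to sum exactly 1),
plus a pseudocount (default 0.01 per entry, renormalized) applied wherever
zeros would break log-odds work. Scores are log₂(p_motif/p_background)
summed over positions — base 2 for bit-interpretable scores; any fixed base
preserves ranks and p-values.

**Site p-values** are exact under the i.i.d. background model up to score
discretization. Per-position scores are mapped onto an integer grid with
step `eps = max_position_range / bins` (default 1000 bins), and the null
distribution of the total grid score is built by convolving the
per-position distributions — the classic MAST-style dynamic programme. A
window's p-value is the survival function at its own grid score, so
p-values are right-continuous, non-increasing in score, and *exactly*
calibrated on the grid: the probability that a background window passes any
achievable threshold equals that threshold's p-value. Two practical
consequences: (i) against enumeration of raw (undiscretized) scores,
p-values can shift by the probability mass inside one grid step — negligible
in the reporting tail (p ≤ 5 × 10⁻⁴) but visible in the bulk; (ii) a PWM
whose columns take few distinct values (e.g. a pure consensus matrix with
one probability for the consensus base and one for the rest) has an
intrinsically coarse score distribution, so no scanner can pass *exactly*
5 × 10⁻⁴ of background windows for it; calibration statements presume a
generic continuous-valued PWM.

Scanning reports all windows with p ≤ `max_p` (default 5 × 10⁻⁴ — the
conventional site-level cutoff for this kind of screen), on both strands;
minus-strand sites are scored via the reverse-complemented matrix and
reported in forward coordinates. A sequence-level E-value cap is accepted
in the configuration for interface compatibility but is a no-op: only the
site-level filter is load-bearing here. Windows containing N are skipped by
default (`n_policy: score_as_background` instead scores N as log-odds 0).
Non-overlapping site selection is greedy by ascending p-value (ties: lower
offset, then + strand); a site is kept iff it shares no base with an
already-kept site.

**Occupancy.** The promoter-level predicted binding is the parameter-free
relative-affinity sum `Σ_w 2^(s(w) − s_max)` over all windows on both
strands: a consensus match contributes 1, weaker windows proportionally
less. This deliberately replaces a fitted thermodynamic occupancy model
(the cited external tool fits a concentration-like parameter): the screen
only consumes occupancy through a Pearson correlation across genes, and the
affinity sum preserves exactly the ranking information a one-motif,
no-cooperativity occupancy model provides while keeping the pipeline free
of fitted parameters. This is the package's one deliberate modelling
deviation and the place where absolute values should not be compared
against thermodynamic tools.

## Association screen and strength comparison

For each motif, Pearson correlations between occupancy and each factor's
enrichment are computed on the intersection of the gene universes (whole
universe by default; per-gene-set runs are a configuration away).
Correlations are categorized high (r > 0.19), negative (r < 0), else
medium; the between-factor difference |r_A − r_B| as shared (< 0.04),
differential (> 0.14), else intermediate. Motifs with constant occupancy
yield *missing* correlations (never 0) and stay in the output flagged
`undefined`. The screen is scale-invariant and invariant under consistent
gene permutations.

The strength comparison pools non-overlapping site p-values (as −log₁₀)
across promoters within each group — co-bound (`both`) vs. single-factor
(`B_only`) — and applies the Mann-Whitney U test with midranks: exact by
enumeration when n ≤ 20 without ties, else the normal approximation with
tie and continuity corrections. Pooling sites (rather than per-promoter
summaries) treats binding sites as the sampled units; the alternative
per-promoter aggregation would weight promoters equally regardless of site
count. The headline one-sided p always tests "co-bound stronger"; the
opposite direction is its own output column, never a silent flip. A group
with zero sites marks the motif untestable. Benjamini–Hochberg adjusted
p-values are reported as an advisory column; the raw α = 0.05 rule is the
decision column. With very small per-group site counts and heavy ties the
tie-corrected normal approximation is mildly anticonservative (measured
type-I ≈ 6% at α = 5% in decoy sweeps); results resting on a handful of
sites should lean on the exact path or the FDR column.

Gene-set summaries report, per set and factor, the bound fraction (factor A
= `both ∪ A_only`, factor B = `both ∪ B_only`) and an upper-tail
hypergeometric enrichment p of the set among bound genes; genes absent from
the universe are counted and reported separately, never silently dropped.

## Synthetic data generator

The generator emulates the study design the analysis assumes: a gene
universe whose promoters are co-bound, single-bound or unbound; one
*planted* motif written into every factor-B-bound promoter with
group-dependent site strength; coverage bumps at the planted sites; peaks
at the true binding positions. Defaults (the generator's study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_chroms`, `chrom_length` | 2 × 200 kb | genome size; 2-kb slot per gene keeps neighbouring promoters separated |
| `n_genes` | 180 | gene universe |
| `f_both`, `f_a_only`, `f_b_only` | 0.25 / 0.15 / 0.25 | class fractions (rest unbound) |
| `sites_per_promoter` | 2 | planted sites per B-bound promoter, 50–450 bp upstream |
| `temp_cobound`, `temp_single` | 0.5 / 1.0 | site-sampling temperature (`p ∝ matrix^(1/T)`; lower = closer to consensus) |
| `peak_amplitude`, `peak_sigma` | 15, 50 bp | Gaussian coverage bumps at planted sites |
| `background_lambda` | 2 | Poisson coverage noise |
| `peak_jitter` | ±50 bp | uniform summit jitter |
| `base_composition` | 0.3/0.2/0.2/0.3 | AT-rich i.i.d. background |
| `motif_width`, `n_decoys` | 8, 20 | planted motif (consensus prob 0.85) plus decoy library |

Sites sit at least 50 bp from the promoter-window edges so that jittered
summits always stay within the 500-bp binding-call radius — the
promoter-proximal geometry high-resolution ChIP methods report. `A_only`
promoters receive coverage at a random promoter position (factor A bound by
other means, no planted motif); `both` promoters receive factor-A signal at
the same planted sites. One master seed drives named per-stage child
streams, so changing one stage's parameters does not perturb another
stage's draws, and the same spec + seed reproduces byte-identical files.

**Decoy screening.** A decoy is by definition unassociated with the binding
classes — but a randomly sampled PWM can genuinely respond to the planted
insertions through windows overlapping the inserted words, the same way
related motifs co-occur in real promoters. Decoy candidates are therefore
screened at generation time: the mean occupancy change caused by one
planted-site insertion into background sequence must not exceed 0.015, and
candidates failing are resampled. After screening, decoy exceedance of the
r > 0.19 threshold matches the permutation null of the screen.

What the generator does **not** emulate, hence what passing tests do not
show about real data: read-level noise and mappability, ChIP-exo strand
asymmetry, chromatin accessibility structure, correlated motif co-occurrence
(real motif libraries contain families of near-duplicates whose screen
correlations travel together), non-i.i.d. genomic background
(CpG/AT isochores, repeats), input-dependent enrichment biases, and
bidirectional-promoter geometry beyond what random placement produces.

## Numerical and degenerate-input choices

- Score discretization: 1000 bins per position; exhaustive enumeration
  replaces the DP in oracle tests for width ≤ 6.
- Nearest-TSS and greedy-site tie-breaks are deterministic (documented
  above), so reruns are bit-identical.
- Constant vectors give missing correlations; empty promoter windows and
  missing chromosomes warn and score 0 (never abort); an empty peak file
  degrades the co-binding table to `B_only / none`; stage failures abort
  the pipeline naming the stage.
- Problem sizes in the test-suite sweeps (e.g. 100 generator seeds at the
  default conditions, 10⁶-window scanner calibration, 1000-repeat null
  calibration) were chosen so the full validation remains a desk-scale
  computation on one CPU.

## Known limitations

- The occupancy score is a ranking statistic, not a fitted occupancy; no
  concentration or cooperativity parameters are estimated.
- The overlap null is a bin model, exactly invariant in counts but only
  approximately under bin-origin shifts; very dense peak sets push it away
  from a position-permutation null.
- Pearson screening on heavy-tailed occupancy distributions has fatter
  null tails than t-theory suggests; the decoy analysis above quantifies
  this and the thresholds are interpreted against the empirical null.
- The Mann-Whitney normal approximation is mildly anticonservative for very
  small, tie-heavy site sets (see above).
- Published genome-scale numbers (peak counts, overlap log-p on real
  chromatin, genome-wide site-strength p-values) depend on the original
  reads and genome build and are outside what this package's synthetic
  conditions can or should reproduce; validation is property-based.
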