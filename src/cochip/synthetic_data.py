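"""Truth-annotated synthetic ChIP datasets.

The generator emulates the study design the analysis assumes: a gene
universe whose promoters are co-bound by factors A and B, bound by one
factor only, or unbound; a planted motif whose sites are written into every
B-bound promoter with group-dependent strength (co-bound promoters receive
sites sampled closer to the consensus than single-factor promoters);
Gaussian-shaped coverage bumps over Poisson background centred on the
planted sites; and peak calls at the true binding positions with uniform
positional jitter.  Decoy motifs are generated but never planted, so the
association screen and strength comparison have a known answer.

One master seed drives a hierarchy of per-stage child streams, so changing
one stage's parameters does not perturb another stage's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formats_io import (BASES, CoverageTrack, GeneRecord, GenomeSequence,
                         Peak, PWMRecord, promoter_interval, revcomp,
                         write_bed_peaks, write_fasta, write_gene_table,
                         write_meme_motifs, write_wiggle)

_STAGES = ("genome", "genes", "classes", "sites", "coverage_A", "coverage_B",
           "peaks", "motifs")

GENE_SLOT = 2000  # bp reserved per gene; keeps promoters of neighbours apart


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 180
    promoter_upstream: int = 500
    f_both: float = 0.25
    f_a_only: float = 0.15
    f_b_only: float = 0.25
    # site planting
    sites_per_promoter: int = 2
    temp_cobound: float = 0.5     # sampling temperature; lower = stronger sites
    temp_single: float = 1.0
    site_margin: int = 50         # bp clear of the promoter-window edges
    # coverage model
    peak_amplitude: float = 15.0
    peak_sigma: float = 50.0
    background_lambda: float = 2.0
    peak_jitter: int = 50
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    # motif library
    motif_width: int = 8
    n_decoys: int = 20

    def validate(self) -> None:
        fr = (self.f_both, self.f_a_only, self.f_b_only)
        if any(f < 0 for f in fr) or sum(fr) > 1:
            raise ValueError("class fractions must be nonnegative and sum to <= 1")
        if self.n_chroms * self.chrom_length < self.n_genes * GENE_SLOT:
            raise ValueError("chromosomes too short for non-overlapping gene "
                             f"placement ({self.n_genes} genes need "
                             f"{self.n_genes * GENE_SLOT} bp)")
        if self.temp_cobound <= 0 or self.temp_single <= 0:
            raise ValueError("temperatures must be > 0")
        if abs(sum(self.base_composition) - 1) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass(frozen=True)
class TruthSite:
    gene_id: str
    motif_id: str
    chrom: str
    start: int        # 0-based genomic
    strand: str
    word: str         # as written on the given strand's forward coordinates
    group: str        # co_bound | single


@dataclass
class TruthTable:
    classes: dict[str, str]
    sites: list[TruthSite]
    planted_motif_id: str
    binding_centers: dict[tuple[str, str], list[int]]  # (factor, gene) -> centers
    expected_enrichment: dict[str, dict[str, float]]   # factor -> gene -> mean


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genome: GenomeSequence
    genes: list[GeneRecord]
    motifs: list[PWMRecord]
    peaks: dict[str, list[Peak]]          # factor -> peaks
    coverage: dict[str, CoverageTrack]    # factor -> track
    truth: TruthTable

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.tsv",
            "motifs": outdir / "motifs.meme",
            "peaks_A": outdir / "peaks_A.bed",
            "peaks_B": outdir / "peaks_B.bed",
            "coverage_A": outdir / "coverage_A.wig",
            "coverage_B": outdir / "coverage_B.wig",
            "truth_genes": outdir / "truth_genes.tsv",
            "truth_sites": outdir / "truth_sites.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gene_table(self.genes, paths["genes"])
        write_meme_motifs(self.motifs, paths["motifs"])
        write_bed_peaks(self.peaks["A"], paths["peaks_A"])
        write_bed_peaks(self.peaks["B"], paths["peaks_B"])
        write_wiggle(self.coverage["A"], paths["coverage_A"])
        write_wiggle(self.coverage["B"], paths["coverage_B"])
        with open(paths["truth_genes"], "w") as fh:
            fh.write("gene_id\tclass\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{self.truth.classes[g.gene_id]}\n")
        with open(paths["truth_sites"], "w") as fh:
            fh.write("gene_id\tmotif_id\tchrom\tstart\tstrand\tword\tgroup\n")
            for s in self.truth.sites:
                fh.write(f"{s.gene_id}\t{s.motif_id}\t{s.chrom}\t{s.start}"
                         f"\t{s.strand}\t{s.word}\t{s.group}\n")
        return paths


# ---------------------------------------------------------------------------
# Motif library and site sampling
# ---------------------------------------------------------------------------

def _insertion_response(decoy: PWMRecord, planted: PWMRecord,
                        rng: np.random.Generator,
                        comp: Sequence[float], n_trials: int = 100) -> float:
    """Mean change in a decoy's occupancy score caused by writing one
    planted-motif site into background sequence.

    A candidate decoy whose occupancy responds to planted-site insertions is
    not a decoy: it would be genuinely associated with the binding classes
    (the way related motifs co-occur in real promoters).  The response
    includes every window overlapping the insertion, which is where most of
    the cross-talk lives.
    """
    from .motif_engine import ScoreDistribution, occupancy_score

    dist = ScoreDistribution(decoy)
    w = planted.width
    flank = decoy.width + 4
    deltas = np.empty(n_trials)
    for t in range(n_trials):
        codes = rng.choice(4, size=2 * flank + w, p=np.asarray(comp))
        seq = "".join(BASES[i] for i in codes)
        base = occupancy_score(seq, decoy, dist=dist)
        word = sample_site_from_pwm(planted, 1.0, rng)
        if rng.random() < 0.5:
            word = revcomp(word)
        mod = seq[:flank] + word + seq[flank + w:]
        deltas[t] = occupancy_score(mod, decoy, dist=dist) - base
    return float(deltas.mean())


def random_pwm_library(rng: np.random.Generator, n_decoys: int = 20,
                       width: int = 8, consensus_prob: float = 0.85,
                       background: Optional[Sequence[float]] = None,
                       max_decoy_response: float = 0.015
                       ) -> list[PWMRecord]:
    """A planted motif (index 0) plus informative random decoys.

    The planted motif has a random consensus with per-position consensus
    probability ``consensus_prob``; decoys are Dirichlet-sampled rows with
    comparable information-content spread.  Each decoy candidate is screened
    for cross-talk with the planted motif (mean occupancy response to a
    planted-site insertion must stay below ``max_decoy_response``) and
    resampled otherwise, so decoys are unassociated by construction.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    motifs: list[PWMRecord] = []
    consensus = rng.integers(0, 4, size=width)
    mat = np.full((width, 4), (1 - consensus_prob) / 3)
    mat[np.arange(width), consensus] = consensus_prob
    planted = PWMRecord("motif_000", mat, bg)
    motifs.append(planted)
    for i in range(n_decoys):
        for _attempt in range(50):
            rows = rng.dirichlet(np.full(4, 0.7), size=width)
            rows = np.clip(rows, 1e-4, None)
            rows = rows / rows.sum(axis=1, keepdims=True)
            decoy = PWMRecord(f"motif_{i + 1:03d}", rows, bg)
            if _insertion_response(decoy, planted, rng, bg) <= max_decoy_response:
                break
        else:
            raise RuntimeError("could not sample an unassociated decoy motif")
        motifs.append(decoy)
    return motifs


def sample_site_from_pwm(pwm: PWMRecord, temperature: float,
                         rng: np.random.Generator) -> str:
    """Sample a site word position-independently from ``p ∝ matrix**(1/T)``.

    ``T → 0`` converges to the consensus word; ``T = 1`` samples the PWM
    itself; larger ``T`` flattens toward uniform.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    logp = np.log(np.clip(pwm.regularized, 1e-300, None)) / temperature
    logp = logp - logp.max(axis=1, keepdims=True)
    probs = np.exp(logp)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return "".join(BASES[rng.choice(4, p=row)] for row in probs)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STAGES, children)}


def _place_genes(spec: SyntheticSpec, rng: np.random.Generator,
                 chrom_names: list[str]) -> list[GeneRecord]:
    slots_per_chrom = spec.chrom_length // GENE_SLOT
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneRecord] = []
    idx = 0
    for chrom, n in zip(chrom_names, per_chrom):
        if n > slots_per_chrom:
            raise ValueError(f"cannot place {n} genes in {slots_per_chrom} slots "
                             f"on {chrom}")
        slots = np.sort(rng.choice(slots_per_chrom, size=n, replace=False))
        for slot in slots:
            tss0 = int(slot) * GENE_SLOT + int(rng.integers(700, 1301))
            strand = "+" if rng.random() < 0.5 else "-"
            body = int(rng.integers(500, 1501))
            if strand == "+":
                span = (tss0, min(tss0 + body, spec.chrom_length))
            else:
                span = (max(tss0 + 1 - body, 0), tss0 + 1)
            genes.append(GeneRecord(f"g{idx:04d}", chrom, strand, tss0 + 1, span))
            idx += 1
    return genes


def _plant_sites(spec: SyntheticSpec, rng: np.random.Generator,
                 genome_codes: dict[str, np.ndarray],
                 genes: Sequence[GeneRecord], classes: dict[str, str],
                 planted: PWMRecord) -> list[TruthSite]:
    wlen = planted.width
    sites: list[TruthSite] = []
    code_of = {b: i for i, b in enumerate(BASES)}
    for g in genes:
        cls = classes[g.gene_id]
        if cls not in ("both", "B_only"):
            continue
        group = "co_bound" if cls == "both" else "single"
        temp = spec.temp_cobound if cls == "both" else spec.temp_single
        iv = promoter_interval(g, spec.promoter_upstream,
                               chrom_length=spec.chrom_length)
        assert iv is not None
        lo = iv[0] + spec.site_margin
        hi = iv[1] - spec.site_margin - wlen
        placed: list[tuple[int, int]] = []
        for _ in range(spec.sites_per_promoter):
            for _attempt in range(200):
                start = int(rng.integers(lo, hi + 1))
                if all(start + wlen <= a or start >= b for a, b in placed):
                    break
            else:
                raise RuntimeError(
                    f"could not place {spec.sites_per_promoter} non-overlapping "
                    f"sites in promoter of {g.gene_id}")
            placed.append((start, start + wlen))
            word = sample_site_from_pwm(planted, temp, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            written = word if strand == "+" else revcomp(word)
            arr = genome_codes[g.chrom]
            arr[start:start + wlen] = [code_of[c] for c in written]
            sites.append(TruthSite(g.gene_id, planted.motif_id, g.chrom,
                                   start, strand, written, group))
        placed.sort()
    return sites


def _gaussian_bump(length: int, center: int, amplitude: float, sigma: float
                   ) -> tuple[int, int, np.ndarray]:
    half = int(4 * sigma)
    lo, hi = max(center - half, 0), min(center + half + 1, length)
    x = np.arange(lo, hi)
    return lo, hi, amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def generate_dataset(spec: SyntheticSpec,
                     pwm_library: Optional[Sequence[PWMRecord]] = None
                     ) -> SyntheticDataset:
    """Generate a complete dataset; byte-identical for identical spec+seed."""
    spec.validate()
    rngs = _stage_rngs(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]

    if pwm_library is None:
        pwm_library = random_pwm_library(rngs["motifs"], spec.n_decoys,
                                         spec.motif_width,
                                         background=None)
    motifs = list(pwm_library)
    planted = motifs[0]

    comp = np.asarray(spec.base_composition)
    genome_codes = {c: rngs["genome"].choice(4, size=spec.chrom_length, p=comp)
                    .astype(np.int8) for c in chrom_names}

    genes = _place_genes(spec, rngs["genes"], chrom_names)

    p = [spec.f_both, spec.f_a_only, spec.f_b_only,
         1 - spec.f_both - spec.f_a_only - spec.f_b_only]
    draw = rngs["classes"].choice(4, size=len(genes), p=p)
    labels = ("both", "A_only", "B_only", "none")
    classes = {g.gene_id: labels[draw[i]] for i, g in enumerate(genes)}

    truth_sites = _plant_sites(spec, rngs["sites"], genome_codes, genes,
                               classes, planted)

    # binding centres: B binds planted sites; A co-binds them on 'both'
    # promoters and binds one promoter position of its own on 'A_only' genes
    site_centers: dict[str, list[int]] = {}
    for s in truth_sites:
        site_centers.setdefault(s.gene_id, []).append(s.start + planted.width // 2)
    centers: dict[tuple[str, str], list[int]] = {}
    for g in genes:
        cls = classes[g.gene_id]
        if cls in ("both", "B_only"):
            centers[("B", g.gene_id)] = list(site_centers[g.gene_id])
        if cls == "both":
            centers[("A", g.gene_id)] = list(site_centers[g.gene_id])
        elif cls == "A_only":
            iv = promoter_interval(g, spec.promoter_upstream,
                                   chrom_length=spec.chrom_length)
            assert iv is not None
            pos = int(rngs["sites"].integers(iv[0] + spec.site_margin,
                                             iv[1] - spec.site_margin))
            centers[("A", g.gene_id)] = [pos]

    gene_by_id = {g.gene_id: g for g in genes}
    coverage: dict[str, CoverageTrack] = {}
    for factor in ("A", "B"):
        rng = rngs[f"coverage_{factor}"]
        data = {c: rng.poisson(spec.background_lambda, spec.chrom_length)
                .astype(float) for c in chrom_names}
        for (f, gid), cs in centers.items():
            if f != factor:
                continue
            chrom = gene_by_id[gid].chrom
            for c in cs:
                lo, hi, bump = _gaussian_bump(spec.chrom_length, c,
                                              spec.peak_amplitude,
                                              spec.peak_sigma)
                data[chrom][lo:hi] += bump
        coverage[factor] = CoverageTrack(data)

    rng_peaks = rngs["peaks"]
    half_w = max(int(2 * spec.peak_sigma), 1)
    peaks: dict[str, list[Peak]] = {"A": [], "B": []}
    for factor in ("A", "B"):
        k = 0
        for g in genes:  # deterministic gene order for reproducibility
            cs = centers.get((factor, g.gene_id))
            if not cs:
                continue
            for c in cs:
                jit = int(rng_peaks.integers(-spec.peak_jitter,
                                             spec.peak_jitter + 1))
                summit = int(np.clip(c + jit, 0, spec.chrom_length - 1))
                start = max(summit - half_w, 0)
                end = min(summit + half_w + 1, spec.chrom_length)
                peaks[factor].append(Peak(g.chrom, start, end,
                                          spec.peak_amplitude, summit,
                                          f"{factor}_peak_{k + 1}"))
                k += 1

    # expected promoter enrichment: best window_w=50 average of one bump
    # plus background, vs background alone for unbound promoters
    x = np.arange(-25, 25)
    bump_factor = float(np.mean(np.exp(-0.5 * (x / spec.peak_sigma) ** 2)))
    expected = {}
    for factor in ("A", "B"):
        expected[factor] = {
            g.gene_id: spec.background_lambda
            + (spec.peak_amplitude * bump_factor
               if (factor, g.gene_id) in centers else 0.0)
            for g in genes}

    genome = GenomeSequence({
        c: "".join(BASES[i] for i in genome_codes[c]) for c in chrom_names})
    truth = TruthTable(classes, truth_sites, planted.motif_id, centers, expected)
    return SyntheticDataset(spec, genome, genes, motifs, peaks, coverage, truth)


# ---------------------------------------------------------------------------
# Strand-mirror transformation
# ---------------------------------------------------------------------------

def mirror_dataset(ds: SyntheticDataset) -> SyntheticDataset:
    """Reverse-complement the genome and mirror every coordinate and strand.

    All per-gene statistics (co-binding classes, enrichments, occupancy
    scores, correlations) must be invariant under this transformation.
    """
    L = {c: len(s) for c, s in ds.genome.chroms.items()}
    genome = GenomeSequence({c: revcomp(s) for c, s in ds.genome.chroms.items()})
    genes = [GeneRecord(g.gene_id, g.chrom,
                        "-" if g.strand == "+" else "+",
                        L[g.chrom] - g.tss0,
                        (L[g.chrom] - g.span[1], L[g.chrom] - g.span[0]))
             for g in ds.genes]
    peaks = {f: [Peak(p.chrom, L[p.chrom] - p.end, L[p.chrom] - p.start, p.score,
                      None if p.summit is None else L[p.chrom] - 1 - p.summit,
                      p.name)
                 for p in ps]
             for f, ps in ds.peaks.items()}
    coverage = {f: CoverageTrack({c: t.get(c, L[c])[::-1].copy()
                                  for c in ds.genome.chroms})
                for f, t in ds.coverage.items()}
    sites = [TruthSite(s.gene_id, s.motif_id, s.chrom,
                       L[s.chrom] - (s.start + len(s.word)),
                       "-" if s.strand == "+" else "+",
                       revcomp(s.word), s.group)
             for s in ds.truth.sites]
    chrom_of = {g.gene_id: g.chrom for g in ds.genes}
    centers = {key: [L[chrom_of[key[1]]] - 1 - c for c in cs]
               for key, cs in ds.truth.binding_centers.items()}
    truth = TruthTable(dict(ds.truth.classes), sites, ds.truth.planted_motif_id,
                       centers, ds.truth.expected_enrichment)
    return SyntheticDataset(ds.spec, genome, genes, ds.motifs, peaks,
                            coverage, truth)


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    class_accuracy: float
    confusion: "object"            # pandas DataFrame: truth x called
    planted_rank_a: Optional[int]
    planted_rank_b: Optional[int]
    planted_r_a: Optional[float]
    planted_r_b: Optional[float]
    strength_significant: Optional[bool]
    strength_direction_agrees: Optional[bool]


def evaluate_recovery(truth: TruthTable, cobinding, screen=None,
                      strength=None, spec: Optional[SyntheticSpec] = None
                      ) -> RecoveryReport:
    """Score pipeline outputs against the generator truth."""
    import pandas as pd

    called = cobinding.classes
    if set(called) != set(truth.classes):
        raise ValueError("gene universe mismatch between outputs and truth")
    genes = sorted(called)
    t = [truth.classes[g] for g in genes]
    c = [called[g] for g in genes]
    accuracy = float(np.mean([a == b for a, b in zip(t, c)]))
    confusion = pd.crosstab(pd.Series(t, name="truth"),
                            pd.Series(c, name="called"))
    rank_a = rank_b = r_a = r_b = None
    if screen is not None:
        planted = truth.planted_motif_id
        for col, store in (("r_A", "a"), ("r_B", "b")):
            order = screen.sort_values(col, ascending=False,
                                       na_position="last")["motif_id"].tolist()
            rank = order.index(planted) + 1
            r = float(screen.loc[screen.motif_id == planted, col].iloc[0])
            if store == "a":
                rank_a, r_a = rank, r
            else:
                rank_b, r_b = rank, r
    significant = agrees = None
    if strength is not None and strength.testable:
        significant = bool(strength.significant)
        expected_dir = None
        if spec is not None:
            expected_dir = ("co_bound" if spec.temp_cobound < spec.temp_single
                            else "single")
        agrees = (strength.direction == expected_dir
                  if expected_dir is not None else None)
    return RecoveryReport(accuracy, confusion, rank_a, rank_b, r_a, r_b,
                          significant, agrees)
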