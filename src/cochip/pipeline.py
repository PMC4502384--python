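"""Deterministic, provenance-stamped orchestration of the analysis stages:
annotate → classify → enrich → scan → screen → compare-strength → summarize.

Every output TSV carries a provenance header (tool version, config hash);
a machine-readable manifest lists all outputs with checksums, so a rerun
with identical inputs and configuration reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .association_stats import (ALPHA, bh_fdr, binding_fraction_summary,
                                motif_association_screen,
                                site_strength_comparison)
from .formats_io import (GenomeSequence, promoter_sequence, read_bed_peaks,
                         read_coverage, read_fasta, read_gene_table,
                         read_meme_motifs)
from .motif_engine import (DEFAULT_MAX_P, ScanConfig, ScoreDistribution,
                           find_sites, nonoverlapping_sites, occupancy_score)
from .peak_annotation import (BINDING_MAX_DIST, OVERLAP_THRESHOLD,
                              PROMOTER_WINDOW, assign_peaks_to_genes,
                              classify_cobinding, overlap_peak_sets)
from .promoter_signal import (DEFAULT_WINDOW_W, build_enrichment_table,
                              enrichment_series)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and tunable constants of one pipeline run."""

    genome: Optional[str] = None
    genes: Optional[str] = None
    peaks_a: Optional[str] = None
    peaks_b: Optional[str] = None
    coverage_a: Optional[str] = None
    coverage_b: Optional[str] = None
    motifs: Optional[str] = None
    gene_sets: dict[str, str] = field(default_factory=dict)  # name -> path
    outdir: str = "cochip_out"
    factor_a: str = "A"
    factor_b: str = "B"
    promoter_upstream: int = 500
    annotation_window: tuple[int, int] = PROMOTER_WINDOW
    binding_max_dist: int = BINDING_MAX_DIST
    binding_rule: str = "max_dist"       # or "annotation_window"
    overlap_threshold: int = OVERLAP_THRESHOLD
    enrichment_window_w: int = DEFAULT_WINDOW_W
    scan_max_p: float = DEFAULT_MAX_P
    r_high: float = 0.19
    delta_shared: float = 0.04
    delta_differential: float = 0.14
    strength_alpha: float = ALPHA
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "annotation_window" in raw:
            raw["annotation_window"] = tuple(raw["annotation_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["annotation_window"] = list(self.annotation_window)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def provenance_header(config: PipelineConfig) -> str:
    lines = [f"# cochip {__version__}",
             f"# config_hash = {config.config_hash()}",
             f"# seed = {config.seed}"]
    for key in ("promoter_upstream", "annotation_window", "binding_max_dist",
                "binding_rule", "overlap_threshold", "enrichment_window_w",
                "scan_max_p", "r_high", "delta_shared", "delta_differential",
                "strength_alpha"):
        lines.append(f"# {key} = {getattr(config, key)}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                  lineterminator="\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# In-memory analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    assignments_a: pd.DataFrame
    assignments_b: pd.DataFrame
    cobinding: "object"
    cobinding_df: pd.DataFrame
    enrichment_a: pd.DataFrame
    enrichment_b: pd.DataFrame
    overlap: "object"
    sites_df: pd.DataFrame
    occupancy: pd.DataFrame
    screen: pd.DataFrame
    strength: pd.DataFrame
    strength_results: dict
    fractions: Optional[pd.DataFrame]


def _assignments_frame(assignments) -> pd.DataFrame:
    return pd.DataFrame([{
        "peak_id": a.peak.name or f"{a.peak.chrom}:{a.peak.start}-{a.peak.end}",
        "chrom": a.peak.chrom, "start": a.peak.start, "end": a.peak.end,
        "anchor": a.peak.anchor, "gene_id": a.gene_id or "none",
        "distance": "" if a.distance is None else a.distance,
        "region_label": a.region_label} for a in assignments])


def analyze(genome: GenomeSequence, genes, peaks_a, peaks_b,
            coverage_a, coverage_b, motifs,
            config: PipelineConfig = PipelineConfig(),
            gene_sets: Optional[dict[str, Sequence[str]]] = None
            ) -> AnalysisResult:
    """Run every analysis stage on in-memory objects."""
    lengths = genome.lengths

    assign_a = assign_peaks_to_genes(peaks_a, genes, config.annotation_window)
    assign_b = assign_peaks_to_genes(peaks_b, genes, config.annotation_window)

    if config.binding_rule == "annotation_window":
        # bound = has a peak annotated to the gene with a promoter label
        def bound_set(assigns):
            return {a.gene_id for a in assigns
                    if a.gene_id and a.region_label == "promoter"}
        from .peak_annotation import CoBindingTable
        in_a, in_b = bound_set(assign_a), bound_set(assign_b)
        classes = {}
        for g in genes:
            a, b = g.gene_id in in_a, g.gene_id in in_b
            classes[g.gene_id] = ("both" if a and b else "A_only" if a
                                  else "B_only" if b else "none")
        cobinding = CoBindingTable(classes, config.factor_a, config.factor_b,
                                   config.binding_max_dist)
    else:
        cobinding = classify_cobinding(peaks_a, peaks_b, genes,
                                       config.binding_max_dist,
                                       config.factor_a, config.factor_b)
    cobinding_df = pd.DataFrame(
        sorted(cobinding.classes.items()), columns=["gene_id", "class"])

    enr_a = build_enrichment_table(coverage_a, genes, config.factor_a,
                                   config.promoter_upstream, 0,
                                   config.enrichment_window_w, lengths)
    enr_b = build_enrichment_table(coverage_b, genes, config.factor_b,
                                   config.promoter_upstream, 0,
                                   config.enrichment_window_w, lengths)

    def enr_frame(recs):
        return pd.DataFrame([{
            "gene_id": r.gene_id, "factor": r.factor,
            "enrichment": r.enrichment, "window_w": r.window_w,
            "interval": ("" if r.interval is None else
                         f"{r.interval[0]}:{r.interval[1]}-{r.interval[2]}")}
            for r in recs])

    genome_size = sum(lengths.values())
    overlap = overlap_peak_sets(peaks_a, peaks_b, config.overlap_threshold,
                                genome_size) if peaks_a and peaks_b else None

    promoters = {g.gene_id: promoter_sequence(genome, g,
                                              config.promoter_upstream)
                 for g in genes}
    scan_cfg = ScanConfig(max_p=config.scan_max_p)
    site_rows = []
    occ_rows: dict[str, dict[str, float]] = {}
    sites_by_motif: dict[str, tuple[list, list]] = {}
    for pwm in motifs:
        dist = ScoreDistribution(pwm)
        occ_rows[pwm.motif_id] = {}
        kept_sites: list = []
        kept_genes: list = []
        for gid, seq in promoters.items():
            occ_rows[pwm.motif_id][gid] = occupancy_score(
                seq, pwm, scan_cfg.both_strands, dist)
            hits = find_sites(seq, pwm, scan_cfg, sequence_id=gid, dist=dist)
            for s in nonoverlapping_sites(hits):
                kept_sites.append(s)
                kept_genes.append(gid)
                site_rows.append({
                    "sequence_id": gid, "motif_id": pwm.motif_id,
                    "offset": s.offset, "strand": s.strand,
                    "score": s.log_odds_score, "p_value": s.p_value})
        sites_by_motif[pwm.motif_id] = (kept_sites, kept_genes)
    sites_df = pd.DataFrame(site_rows, columns=[
        "sequence_id", "motif_id", "offset", "strand", "score", "p_value"])
    occupancy = pd.DataFrame.from_dict(occ_rows, orient="index")

    screen = motif_association_screen(
        occupancy,
        enrichment_series(enr_a),
        enrichment_series(enr_b))

    strength_results = {}
    strength_rows = []
    for pwm in motifs:
        kept_sites, kept_genes = sites_by_motif[pwm.motif_id]
        res = site_strength_comparison(kept_sites, kept_genes, cobinding,
                                       pwm.motif_id, config.strength_alpha)
        strength_results[pwm.motif_id] = res
        strength_rows.append({
            "motif_id": pwm.motif_id, "n_cobound": res.n_cobound,
            "n_single": res.n_single,
            "U": "" if res.u_statistic is None else res.u_statistic,
            "p_cobound_greater": ("" if res.p_cobound_greater is None
                                  else res.p_cobound_greater),
            "p_single_greater": ("" if res.p_single_greater is None
                                 else res.p_single_greater),
            "direction": res.direction or "untestable",
            "significant": ("" if res.significant is None
                            else bool(res.significant))})
    strength = pd.DataFrame(strength_rows)
    testable = strength["p_cobound_greater"] != ""
    fdr = pd.Series([""] * len(strength), dtype=object)
    if testable.any():
        fdr.loc[testable] = bh_fdr(
            strength.loc[testable, "p_cobound_greater"].astype(float))
    strength["fdr_bh"] = fdr

    fractions = None
    if gene_sets:
        fractions = binding_fraction_summary(gene_sets, cobinding)

    return AnalysisResult(_assignments_frame(assign_a),
                          _assignments_frame(assign_b),
                          cobinding, cobinding_df, enr_frame(enr_a),
                          enr_frame(enr_b), overlap, sites_df, occupancy,
                          screen, strength, strength_results, fractions)


# ---------------------------------------------------------------------------
# File-level pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Read inputs per config, run every stage, write TSVs and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        genome = read_fasta(config.genome)
        genes = read_gene_table(config.genes)
        peaks_a = read_bed_peaks(config.peaks_a) if config.peaks_a else []
        peaks_b = read_bed_peaks(config.peaks_b) if config.peaks_b else []
        cov_a = read_coverage(config.coverage_a).pad_to(genome.lengths) \
            if config.coverage_a else None
        cov_b = read_coverage(config.coverage_b).pad_to(genome.lengths) \
            if config.coverage_b else None
        motifs = read_meme_motifs(config.motifs) if config.motifs else []
        gene_sets = {}
        for name, path in config.gene_sets.items():
            with open(path) as fh:
                gene_sets[name] = [l.strip() for l in fh if l.strip()]
        stage = "analyze"
        from .formats_io import CoverageTrack
        result = analyze(genome, genes, peaks_a, peaks_b,
                         cov_a or CoverageTrack(), cov_b or CoverageTrack(),
                         motifs, config, gene_sets or None)
        stage = "write-outputs"
        outputs: dict[str, Path] = {}

        def emit(name: str, df: pd.DataFrame) -> None:
            path = outdir / f"{name}.tsv"
            write_tsv(df, path, config)
            outputs[name] = path

        emit("assignments_A", result.assignments_a)
        emit("assignments_B", result.assignments_b)
        emit("cobinding", result.cobinding_df)
        emit("enrichment_A", result.enrichment_a)
        emit("enrichment_B", result.enrichment_b)
        emit("sites", result.sites_df)
        occ = result.occupancy.reset_index(names="motif_id")
        emit("occupancy", occ)
        emit("screen", result.screen)
        emit("strength", result.strength)
        if result.overlap is not None:
            ov = result.overlap
            emit("overlap", pd.DataFrame([{
                "factor_A": config.factor_a, "factor_B": config.factor_b,
                "n_A": ov.n_a, "n_B": ov.n_b, "n_overlap": ov.n_overlap,
                "expected_overlap": ov.expected_overlap,
                "log10_p": ov.log10_p, "threshold": ov.threshold,
                "genome_size": ov.genome_size}]))
        if result.fractions is not None:
            emit("binding_fractions", result.fractions)

        manifest = {
            "tool": "cochip", "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "outputs": {name: {"path": str(p), "sha256": sha256_file(p)}
                        for name, p in outputs.items()},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
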