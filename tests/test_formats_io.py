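"""Format readers/writers: conventions, error contracts, round-trips."""

import numpy as np
import pytest

from cochip.formats_io import (CoverageTrack, FormatError, GeneRecord,
                               GenomeSequence, Peak, PWMRecord,
                               promoter_interval, promoter_sequence,
                               read_bed_peaks, read_coverage, read_fasta,
                               read_gene_table, read_meme_motifs, revcomp,
                               write_bed_peaks, write_bedgraph, write_fasta,
                               write_gene_table, write_meme_motifs,
                               write_wiggle)

from conftest import random_genome


# ---------------------------------------------------------------------- FASTA

def test_fasta_parses_records_and_uppercases(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chr1 some description\nacgt\n>chr2\nNNNN\n")
    g = read_fasta(p)
    assert set(g.chroms) == {"chr1", "chr2"}
    assert g["chr1"] == "ACGT"
    assert g["chr2"] == "NNNN"
    assert g.lengths == {"chr1": 4, "chr2": 4}


@pytest.mark.parametrize("content,msg", [
    ("", "empty"),
    (">a\nACGT\n>a\nTTTT\n", "duplicate"),
    (">a\nACXT\n", "non-IUPAC"),
])
def test_fasta_error_contracts(tmp_path, content, msg):
    p = tmp_path / "bad.fa"
    p.write_text(content)
    with pytest.raises(FormatError, match=msg):
        read_fasta(p)


def test_fasta_round_trip_many_random_genomes(tmp_path, rng):
    for i in range(100):
        g = random_genome(rng, n_chroms=int(rng.integers(1, 4)))
        path = tmp_path / f"rt{i}.fa"
        write_fasta(g, path)
        assert read_fasta(path).chroms == g.chroms


# ------------------------------------------------------------------------ BED

def test_bed_minimal_and_scored_lines(tmp_path):
    p = tmp_path / "p.bed"
    p.write_text("# comment\ntrack name=x\nchr1\t100\t200\n"
                 "chr1\t100\t200\tp1\t37\n")
    peaks = read_bed_peaks(p)
    assert peaks[0] == Peak("chr1", 100, 200, 0.0, None, None)
    assert peaks[1].score == 37
    assert peaks[1].name == "p1"


def test_bed_summit_column_narrowpeak_style(tmp_path):
    p = tmp_path / "p.bed"
    p.write_text("chr1\t100\t200\tp1\t5\t.\t0\t0\t0\t30\n")
    peaks = read_bed_peaks(p, summit_col=9)
    assert peaks[0].summit == 130


@pytest.mark.parametrize("line", ["chr1\t200\t100", "chr1\tx\t200"])
def test_bed_error_contracts(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text(line + "\n")
    with pytest.raises(FormatError, match=":1"):
        read_bed_peaks(p)


def test_bed_round_trip(tmp_path, rng):
    peaks = []
    for i in range(50):
        s = int(rng.integers(0, 10000))
        e = s + int(rng.integers(1, 500))
        summit = int(rng.integers(s, e)) if rng.random() < 0.5 else None
        peaks.append(Peak("chr1", s, e, float(rng.integers(0, 100)),
                          summit, f"p{i}"))
    path = tmp_path / "rt.bed"
    write_bed_peaks(peaks, path)
    back = read_bed_peaks(path, summit_col=6)
    assert back == peaks


# ---------------------------------------------------------------- gene tables

def test_gene_table_coordinate_conversion(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text("gene_id\tchrom\tstrand\ttss\tstart\tend\n"
                 "g1\tchr1\t+\t1000\t1000\t3000\n")
    (g,) = read_gene_table(p)
    assert g.tss == 1000 and g.span == (999, 3000)


def test_gff3_minus_strand_tss_rule(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("##gff-version 3\n"
                 "chr1\t.\tgene\t1000\t3000\t.\t-\t.\tID=g1;Name=foo\n"
                 "chr1\t.\texon\t1000\t1500\t.\t-\t.\tParent=g1\n")
    (g,) = read_gene_table(p)
    assert g.tss == 3000 and g.strand == "-" and g.span == (999, 3000)


@pytest.mark.parametrize("row,msg", [
    ("g1\tchr1\t*\t10\t10\t20", "strand"),
    ("g1\tchr1\t+\t10\t10\t20\ng1\tchr1\t+\t30\t30\t40", "duplicate"),
])
def test_gene_table_error_contracts(tmp_path, row, msg):
    p = tmp_path / "bad.tsv"
    p.write_text(row + "\n")
    with pytest.raises(FormatError, match=msg):
        read_gene_table(p)


def test_gene_table_round_trip(tmp_path, rng):
    genes = []
    for i in range(20):
        tss0 = int(rng.integers(500, 50000))
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(100, 2000))
        span = (tss0, tss0 + body) if strand == "+" else (tss0 + 1 - body, tss0 + 1)
        genes.append(GeneRecord(f"g{i}", "chr1", strand, tss0 + 1, span))
    path = tmp_path / "rt.tsv"
    write_gene_table(genes, path)
    assert read_gene_table(path) == genes


# ------------------------------------------------------------------- coverage

def test_fixedstep_is_one_based(tmp_path):
    p = tmp_path / "c.wig"
    p.write_text("fixedStep chrom=chr1 start=11 step=1\n5\n5\n")
    track = read_coverage(p)
    vec = track.get("chr1", 12)
    assert vec[10] == 5 and vec[11] == 5 and vec[:10].sum() == 0


def test_bedgraph_is_zero_based_half_open(tmp_path):
    p = tmp_path / "c.bg"
    p.write_text("chr1\t0\t3\t2.5\n")
    vec = read_coverage(p).get("chr1", 4)
    assert list(vec) == [2.5, 2.5, 2.5, 0.0]


def test_bedgraph_overlap_is_error(tmp_path):
    p = tmp_path / "c.bg"
    p.write_text("chr1\t0\t3\t2.5\nchr1\t2\t4\t1.0\n")
    with pytest.raises(FormatError, match="overlap"):
        read_coverage(p)


def test_wiggle_span_exceeding_step_is_error(tmp_path):
    p = tmp_path / "c.wig"
    p.write_text("fixedStep chrom=chr1 start=1 step=2 span=5\n1\n")
    with pytest.raises(FormatError, match="span"):
        read_coverage(p)


def test_variablestep_dialect(tmp_path):
    p = tmp_path / "c.wig"
    p.write_text("variableStep chrom=chr1 span=2\n5\t1.5\n9\t2\n")
    vec = read_coverage(p).get("chr1", 12)
    assert list(vec[4:6]) == [1.5, 1.5] and list(vec[8:10]) == [2.0, 2.0]
    assert vec.sum() == pytest.approx(7.0)


def test_wiggle_and_bedgraph_dialects_agree(tmp_path, rng):
    """The same random track written in both dialects parses identically."""
    for i in range(20):
        n = int(rng.integers(20, 200))
        vec = rng.poisson(1.0, size=n).astype(float)
        track = CoverageTrack({"chrX": vec})
        wig, bg = tmp_path / f"{i}.wig", tmp_path / f"{i}.bg"
        write_wiggle(track, wig)
        write_bedgraph(track, bg)
        v1 = read_coverage(wig).get("chrX", n)
        v2 = read_coverage(bg).get("chrX", n)
        np.testing.assert_allclose(v1, vec, rtol=1e-6)
        np.testing.assert_allclose(v2, vec, rtol=1e-6)


# ----------------------------------------------------------------------- MEME

MEME_ONE = """MEME version 4

ALPHABET= ACGT

MOTIF m1
letter-probability matrix: alength= 4 w= 2
1.0 0.0 0.0 0.0
0.0 1.0 0.0 0.0
"""


def test_meme_regularization_contract(tmp_path):
    p = tmp_path / "m.meme"
    p.write_text(MEME_ONE)
    (m,) = read_meme_motifs(p, pseudocount=0.01)
    reg = m.regularized
    np.testing.assert_allclose(reg.sum(axis=1), 1.0, atol=1e-9)
    assert reg.max() < 1.0
    assert np.all(reg > 0)
    # no background line -> uniform default
    np.testing.assert_allclose(m.background, 0.25)


def test_meme_background_line_used(tmp_path):
    p = tmp_path / "m.meme"
    p.write_text(MEME_ONE.replace(
        "MOTIF m1",
        "Background letter frequencies\nA 0.3 C 0.2 G 0.2 T 0.3\n\nMOTIF m1"))
    (m,) = read_meme_motifs(p)
    np.testing.assert_allclose(m.background, [0.3, 0.2, 0.2, 0.3])


@pytest.mark.parametrize("mutate,msg", [
    (lambda s: s.replace("0.0 1.0 0.0 0.0", "0.0 0.8 0.0 0.0"), "sums to"),
    (lambda s: s.replace("w= 2", "w= 3"), "w="),
])
def test_meme_error_contracts(tmp_path, mutate, msg):
    p = tmp_path / "bad.meme"
    p.write_text(mutate(MEME_ONE))
    with pytest.raises(FormatError, match=msg):
        read_meme_motifs(p)


def test_meme_parser_agrees_with_biopython_minimal(tmp_path, rng):
    """Independent cross-check of the MEME-minimal reader against
    Bio.motifs' parser on files our writer emits."""
    from Bio import motifs as bio_motifs

    pwms = [PWMRecord(f"m{i}", rng.dirichlet(np.ones(4), size=6),
                      np.array([0.3, 0.2, 0.2, 0.3])) for i in range(4)]
    path = tmp_path / "x.meme"
    write_meme_motifs(pwms, path)
    ours = read_meme_motifs(path)
    with open(path) as fh:
        theirs = bio_motifs.parse(fh, "minimal")
    assert [m.motif_id for m in ours] == [m.name for m in theirs]
    for a, b in zip(ours, theirs):
        bio_mat = np.array([[b.pwm[base][j] for base in "ACGT"]
                            for j in range(b.length)])
        np.testing.assert_allclose(a.matrix, bio_mat, atol=1e-6)


def test_meme_round_trip(tmp_path, rng):
    motifs = []
    for i in range(10):
        w = int(rng.integers(4, 12))
        mat = rng.dirichlet(np.ones(4), size=w)
        motifs.append(PWMRecord(f"m{i}", mat, np.array([0.3, 0.2, 0.2, 0.3])))
    path = tmp_path / "rt.meme"
    write_meme_motifs(motifs, path)
    back = read_meme_motifs(path)
    for a, b in zip(motifs, back):
        assert a.motif_id == b.motif_id
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-9)
        np.testing.assert_allclose(a.background, b.background, atol=1e-6)


# ----------------------------------------------------------- promoter windows

def test_promoter_interval_plus_strand():
    g = GeneRecord("g", "chr1", "+", 1000, (999, 2000))
    assert promoter_interval(g, upstream=500) == (499, 999)


def test_promoter_interval_minus_strand_mirrors():
    g = GeneRecord("g", "chr1", "-", 1000, (500, 1000))
    assert promoter_interval(g, upstream=500) == (1000, 1500)


def test_promoter_interval_truncates_at_chromosome_start():
    g = GeneRecord("g", "chr1", "+", 100, (99, 600))
    assert promoter_interval(g, upstream=500) == (0, 99)


def test_promoter_interval_empty_is_none_not_error():
    g = GeneRecord("g", "chr1", "+", 1, (0, 100))
    assert promoter_interval(g, upstream=500) is None
    with pytest.raises(ValueError):
        promoter_interval(g, upstream=0, downstream=0)


def test_minus_strand_promoter_sequence_is_reverse_complemented():
    genome = GenomeSequence({"chr1": "AAAAACGTTTTT"})
    g = GeneRecord("g", "chr1", "-", 4, (0, 4))
    seq = promoter_sequence(genome, g, upstream=4)
    assert seq == revcomp(genome["chr1"][4:8])


def test_promoter_interval_mirror_symmetry(rng):
    """Reverse-complementing the genome and flipping strands maps windows
    onto each other."""
    L = 3000
    for _ in range(50):
        tss0 = int(rng.integers(600, L - 600))
        strand = "+" if rng.random() < 0.5 else "-"
        span = (tss0, tss0 + 100) if strand == "+" else (tss0 - 99, tss0 + 1)
        g = GeneRecord("g", "chr1", strand, tss0 + 1, span)
        iv = promoter_interval(g, 500, 100, L)
        gm = GeneRecord("g", "chr1", "-" if strand == "+" else "+",
                        L - tss0, (L - span[1], L - span[0]))
        ivm = promoter_interval(gm, 500, 100, L)
        assert ivm == (L - iv[1], L - iv[0])
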