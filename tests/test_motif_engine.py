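"""PWM scoring, exact site p-values, scanning, site selection, occupancy."""

import itertools

import numpy as np
import pytest

from cochip.formats_io import BASES, PWMRecord, revcomp
from cochip.motif_engine import (MotifSite, ScanConfig, ScoreDistribution,
                                 encode, find_sites, log_odds_matrix,
                                 nonoverlapping_sites, occupancy_score,
                                 site_pvalue_function)


def random_pwm(rng, width, bg=(0.3, 0.2, 0.2, 0.3)):
    mat = rng.dirichlet(np.ones(4), size=width)
    return PWMRecord("m", mat, np.asarray(bg))


def enumerate_words(width):
    return itertools.product(range(4), repeat=width)


# ------------------------------------------------------------------ log-odds

def test_log_odds_closed_forms():
    mat = np.array([[0.25, 0.25, 0.25, 0.25], [0.5, 0.3, 0.1, 0.1]])
    pwm = PWMRecord("m", mat, pseudocount=1e-12)
    lo = log_odds_matrix(pwm)
    np.testing.assert_allclose(lo[0], 0.0, atol=1e-9)
    assert lo[1, 0] == pytest.approx(1.0, abs=1e-9)  # log2(0.5/0.25)


def test_log_odds_rejects_zero_background():
    pwm = PWMRecord("m", np.full((2, 4), 0.25),
                    background=np.array([0.5, 0.5, 0.0, 0.0]) + 0)
    # background invariant is checked at construction
    with pytest.raises(Exception):
        log_odds_matrix(PWMRecord("m", np.full((2, 4), 0.25)),
                        background=np.array([0.5, 0.5, 0.0, 0.0]))


def test_max_scoring_word_is_positionwise_argmax(rng):
    for width in (2, 4, 6):
        pwm = random_pwm(rng, width)
        lo = log_odds_matrix(pwm)
        best = max(enumerate_words(width),
                   key=lambda w: lo[np.arange(width), w].sum())
        assert list(best) == list(lo.argmax(axis=1))


# ------------------------------------------------------------- site p-values

def test_width1_pvalues_are_quartiles():
    """Distinct scores per base under uniform background give p in
    {0.25, 0.5, 0.75, 1.0}."""
    pwm = PWMRecord("m", np.array([[0.4, 0.3, 0.2, 0.1]]))
    dist = site_pvalue_function(pwm, bins=1000)
    ps = sorted(dist(dist.log_odds[0, b]) for b in range(4))
    assert ps == pytest.approx([0.25, 0.5, 0.75, 1.0])


def test_width2_pvalues_match_exhaustive_dinucleotides(rng):
    """The spec'd example: uniform background, p within 1/bins of direct
    enumeration over all 16 dinucleotides."""
    pwm = PWMRecord("m", rng.dirichlet(np.ones(4), size=2))
    dist = site_pvalue_function(pwm, bins=1000)
    lo = dist.log_odds
    words = list(enumerate_words(2))
    scores = np.array([lo[[0, 1], list(w)].sum() for w in words])
    for w, s in zip(words, scores):
        p_enum = (0.25 ** 2) * (scores >= s - 1e-12).sum()
        assert dist(s) == pytest.approx(p_enum, abs=1 / dist.bins)


def test_dp_equals_enumeration_on_the_discretized_grid(rng):
    """The DP convolution must reproduce direct enumeration over all 4^w
    words under the same per-position discretization (width <= 6)."""
    for trial in range(10):
        width = int(rng.integers(2, 7))
        pwm = random_pwm(rng, width)
        dist = ScoreDistribution(pwm)
        bg = pwm.background
        ks, probs = [], []
        for word in enumerate_words(width):
            ks.append(int(dist.int_table[np.arange(width), list(word)].sum()))
            probs.append(float(np.prod(bg[list(word)])))
        ks, probs = np.array(ks), np.array(probs)
        for k in range(dist.max_int + 1):
            p_enum = probs[ks >= k].sum()
            assert float(dist.sf[k]) == pytest.approx(p_enum, abs=1e-12)


def test_p_of_max_score_is_product_of_best_base_probs(rng):
    for width in (3, 5, 8):
        pwm = random_pwm(rng, width)
        dist = ScoreDistribution(pwm)
        best = dist.log_odds.argmax(axis=1)
        expected = float(np.prod(pwm.background[best]))
        assert float(dist.pvalue_int(dist.max_int)) == pytest.approx(
            expected, rel=1e-9)


def test_pvalue_function_shape(rng):
    pwm = random_pwm(rng, 5)
    dist = ScoreDistribution(pwm)
    assert dist(dist.min_total - 1) == 1.0
    ps = dist.pvalue_int(np.arange(dist.max_int + 1))
    assert np.all(np.diff(ps) <= 1e-15)  # non-increasing
    assert ps[0] == pytest.approx(1.0)


def test_doubling_bins_barely_moves_reported_site_pvalues(rng):
    """Reported (tail) p-values shift by < 1/bins when bins double."""
    pwm = random_pwm(rng, 8)
    seq = "".join(BASES[i] for i in rng.choice(4, 20000, p=pwm.background))
    cfg1 = ScanConfig(max_p=0.0005, bins=1000)
    cfg2 = ScanConfig(max_p=0.0005, bins=2000)
    s1 = find_sites(seq, pwm, cfg1)
    s2 = {(s.offset, s.strand): s.p_value for s in find_sites(seq, pwm, cfg2)}
    assert s1
    for s in s1:
        other = s2.get((s.offset, s.strand))
        if other is not None:
            assert abs(s.p_value - other) < 1 / 1000


# ------------------------------------------------------------------ scanning

def test_planted_consensus_is_found_with_top_score(rng):
    pwm = random_pwm(rng, 6)
    consensus = pwm.consensus
    bgseq = list("".join(BASES[i] for i in rng.choice(4, 500)))
    bgseq[37:43] = consensus
    sites = find_sites("".join(bgseq), pwm, ScanConfig(max_p=0.05))
    at37 = [s for s in sites if s.offset == 37 and s.strand == "+"]
    assert at37
    assert at37[0].log_odds_score == pytest.approx(
        max(s.log_odds_score for s in sites))


def test_all_n_sequence_yields_no_sites():
    pwm = PWMRecord("m", np.full((4, 4), 0.25))
    assert find_sites("N" * 100, pwm, ScanConfig(max_p=1.0)) == []


def test_short_sequence_yields_empty_list_not_error(simple_pwm):
    assert find_sites("AC", simple_pwm) == []


def test_find_sites_matches_bruteforce_enumeration_scan(rng):
    """Site sets equal a brute-force scan computing every window's p-value
    by direct enumeration on the discretized grid (width <= 6)."""
    for trial in range(5):
        width = int(rng.integers(3, 7))
        pwm = random_pwm(rng, width)
        dist = ScoreDistribution(pwm)
        # enumeration oracle: p for every grid score
        bg = pwm.background
        ks, probs = [], []
        for word in enumerate_words(width):
            ks.append(int(dist.int_table[np.arange(width), list(word)].sum()))
            probs.append(float(np.prod(bg[list(word)])))
        ks, probs = np.array(ks), np.array(probs)

        def p_enum_of(word_codes, table):
            k = int(table[np.arange(width), word_codes].sum())
            return probs[ks >= k].sum()

        max_p = 0.02
        seq = "".join(BASES[i] for i in rng.choice(4, 300, p=bg))
        codes = encode(seq)
        rc_table = dist.int_table[::-1][:, [3, 2, 1, 0]]
        expected = set()
        for off in range(len(seq) - width + 1):
            window = codes[off:off + width]
            if p_enum_of(window, dist.int_table) <= max_p:
                expected.add((off, "+"))
            if p_enum_of(window, rc_table) <= max_p:
                expected.add((off, "-"))
        got = {(s.offset, s.strand)
               for s in find_sites(seq, pwm, ScanConfig(max_p=max_p))}
        assert got == expected


def test_strand_symmetry_of_scan_and_occupancy(rng):
    pwm = random_pwm(rng, 7)
    seq = "".join(BASES[i] for i in rng.choice(4, 400))
    rc = revcomp(seq)
    fwd = find_sites(seq, pwm, ScanConfig(max_p=0.01))
    rev = find_sites(rc, pwm, ScanConfig(max_p=0.01))
    flip = {"+": "-", "-": "+"}
    mirrored = {(len(seq) - s.offset - s.width, flip[s.strand],
                 round(s.log_odds_score, 9), s.p_value) for s in rev}
    original = {(s.offset, s.strand, round(s.log_odds_score, 9), s.p_value)
                for s in fwd}
    assert original == mirrored
    assert occupancy_score(seq, pwm) == pytest.approx(
        occupancy_score(rc, pwm), rel=1e-9)


# ------------------------------------------------------- site selection

def site(offset, p, strand="+", width=8):
    return MotifSite("s", "m", offset, strand, width, -np.log10(p), p)


def test_overlapping_sites_keep_only_strongest():
    kept = nonoverlapping_sites([site(0, 1e-4), site(1, 1e-6)])
    assert [(s.offset, s.p_value) for s in kept] == [(1, 1e-6)]


def test_disjoint_sites_all_kept():
    kept = nonoverlapping_sites([site(0, 1e-4), site(100, 1e-6)])
    assert [s.offset for s in kept] == [0, 100]


def test_greedy_selection_matches_reference_reimplementation(rng):
    for _ in range(50):
        n = int(rng.integers(1, 30))
        sites = [site(int(rng.integers(0, 60)),
                      float(10 ** -rng.uniform(3, 8)),
                      "+" if rng.random() < 0.5 else "-")
                 for _ in range(n)]
        got = nonoverlapping_sites(sites)
        # independent oracle: same greedy order, quadratic overlap test
        chosen = []
        for s in sorted(sites, key=lambda s: (s.p_value, s.offset, s.strand)):
            if all(s.offset + s.width <= c.offset
                   or c.offset + c.width <= s.offset for c in chosen):
                chosen.append(s)
        assert got == sorted(chosen, key=lambda s: (s.offset, s.strand))


# ------------------------------------------------------------------ occupancy

def test_palindromic_consensus_occupancy_is_two():
    # GAATTC-like palindrome as a near-deterministic PWM
    word = "GAATTC"
    mat = np.full((6, 4), 1e-9)
    for j, c in enumerate(word):
        mat[j, BASES.index(c)] = 1 - 3e-9
    pwm = PWMRecord("ecori", mat, pseudocount=1e-9)
    assert occupancy_score(word, pwm) == pytest.approx(2.0, rel=1e-6)


def test_planting_a_consensus_site_increases_occupancy(rng):
    pwm = random_pwm(rng, 6)
    seq = list("".join(BASES[i] for i in rng.choice(4, 200)))
    before = occupancy_score("".join(seq), pwm)
    seq[100:106] = pwm.consensus
    after = occupancy_score("".join(seq), pwm)
    assert after > before


def test_occupancy_equals_bruteforce_window_sum(rng):
    for _ in range(10):
        width = int(rng.integers(3, 9))
        pwm = random_pwm(rng, width)
        lo = log_odds_matrix(pwm)
        s_max = lo.max(axis=1).sum()
        seq = "".join(BASES[i] for i in rng.choice(4, 200))
        codes = encode(seq)
        total = 0.0
        for off in range(len(seq) - width + 1):
            w = codes[off:off + width]
            total += 2.0 ** (lo[np.arange(width), w].sum() - s_max)
            rc = 3 - w[::-1]
            total += 2.0 ** (lo[np.arange(width), rc].sum() - s_max)
        assert occupancy_score(seq, pwm) == pytest.approx(total, abs=1e-9)


def test_scan_config_validation():
    with pytest.raises(ValueError):
        ScanConfig(max_p=0.0)
    with pytest.raises(ValueError):
        ScanConfig(bins=10)
    with pytest.raises(ValueError):
        ScanConfig(n_policy="explode")
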