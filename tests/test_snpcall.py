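"""Unit and property tests of the SNP-calling filter cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpfreq.snpcall import (AlignedRead, ContigAlignment, FilterConfig,
                             call_snps, call_snps_from_pileup,
                             classify_substitution, column_alleles,
                             eligible_contig, flank_ok, homopolymer_excluded)

from conftest import make_alignment, pileup_alignment, random_consensus
from oracles import brute_force_calls


# ---------------------------------------------------------------------------
# eligibility gate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,depth,expected", [
    (100, 10, True),    # both thresholds exactly met
    (99, 50, False),    # below the length gate
    (5000, 9, False),   # below the depth gate
])
def test_contig_eligibility_boundaries(length, depth, expected):
    rng = np.random.default_rng(0)
    cons = random_consensus(rng, length)
    aln = make_alignment(cons, [(0, cons, 30)] * depth)
    assert eligible_contig(aln, FilterConfig()) is expected


# ---------------------------------------------------------------------------
# per-column allele counting under the base-quality rule
# ---------------------------------------------------------------------------

def test_column_counts_unanimous_and_quality_filtered(default_filter):
    cons = "A" * 41
    aln = make_alignment(cons, [(0, cons, 30)] * 10)
    assert column_alleles(aln, 21, default_filter) == {"A": 10}

    # low-quality disagreeing bases are ignored entirely, not disqualifying
    reads = [(0, cons, 30)] * 8 + [(0, "A" * 20 + "G" + "A" * 20, 15)] * 2
    aln = make_alignment(cons, reads)
    assert column_alleles(aln, 21, default_filter) == {"A": 8}


def test_column_counts_tally_gaps_without_quality_requirement(default_filter):
    cons = "A" * 41
    reads = [(0, cons, 30)] * 7 + [(0, "A" * 20 + "-" + "A" * 20, 0)] * 3
    aln = make_alignment(cons, reads)
    assert column_alleles(aln, 21, default_filter) == {"A": 7, "-": 3}


def test_column_position_out_of_range(default_filter):
    aln = make_alignment("ACGT", [(0, "ACGT", 30)])
    with pytest.raises(IndexError):
        column_alleles(aln, 5, default_filter)


# ---------------------------------------------------------------------------
# homopolymer exclusion
# ---------------------------------------------------------------------------

def test_homopolymer_run_of_five_excludes_run_and_neighbours(default_filter):
    #            123456789...
    consensus = "CGAAAAAGTCT"  # A-run of 5 at positions 3..7
    for pos in range(3, 8):
        assert homopolymer_excluded(consensus, pos, default_filter)
    # immediately adjacent positions are also excluded
    assert homopolymer_excluded(consensus, 2, default_filter)
    assert homopolymer_excluded(consensus, 8, default_filter)
    assert not homopolymer_excluded(consensus, 1, default_filter)
    assert not homopolymer_excluded(consensus, 9, default_filter)


def test_homopolymer_run_of_four_not_excluded(default_filter):
    consensus = "CGAAAAGTCTT"  # run of 4 = threshold, not over it
    for pos in range(1, len(consensus) + 1):
        assert not homopolymer_excluded(consensus, pos, default_filter)


def test_position_immediately_downstream_of_six_base_run(default_filter):
    consensus = "CTTTTTTGACG"  # T-run of 6 at positions 2..7
    assert homopolymer_excluded(consensus, 8, default_filter)  # 3' neighbour
    assert not homopolymer_excluded(consensus, 9, default_filter)


# ---------------------------------------------------------------------------
# flank rule
# ---------------------------------------------------------------------------

def test_flank_needs_twenty_bases_each_side(default_filter):
    rng = np.random.default_rng(1)
    cons = random_consensus(rng, 1000)
    aln = make_alignment(cons, [(0, cons, 30)] * 10)
    assert not flank_ok(aln, 20, default_filter)   # only 19 bp upstream
    assert flank_ok(aln, 21, default_filter)


def test_single_low_quality_flank_base_fails(default_filter):
    rng = np.random.default_rng(2)
    cons = random_consensus(rng, 1000)
    cq = [40] * 1000
    cq[505] = 10  # 0-based; inside the downstream flank of position 500
    aln = make_alignment(cons, [(0, cons, 30)] * 10, consensus_quality=cq)
    assert not flank_ok(aln, 500, default_filter)
    assert flank_ok(aln, 480, default_filter)  # dip outside this site's window


def test_consensus_n_in_flank_fails(default_filter):
    rng = np.random.default_rng(3)
    cons = list(random_consensus(rng, 200))
    cons[110] = "N"
    aln = make_alignment("".join(cons), [(0, "".join(cons), 30)] * 10)
    assert not flank_ok(aln, 100, default_filter)  # N at 0-based 110 is in flank
    assert flank_ok(aln, 140, default_filter)


# ---------------------------------------------------------------------------
# the caller
# ---------------------------------------------------------------------------

def _clean_consensus(rng, length):
    """Consensus with no homopolymer run over 2, so no exclusion zones."""
    out = [rng.choice(list("ACGT"))]
    while len(out) < length:
        b = rng.choice(list("ACGT"))
        if b != out[-1]:
            out.append(b)
    return "".join(out)


def test_identical_reads_give_no_calls(default_filter):
    rng = np.random.default_rng(4)
    cons = _clean_consensus(rng, 300)
    aln = pileup_alignment(cons, depth=20)
    assert call_snps(aln, default_filter) == []


def test_single_planted_site_called_exactly(default_filter):
    rng = np.random.default_rng(5)
    cons = _clean_consensus(rng, 300)
    pos = 150
    major = cons[pos - 1]
    minor = "A" if major != "A" else "G"
    aln = pileup_alignment(cons, depth=30, variants={pos: [(minor, 3)]})
    calls = call_snps(aln, default_filter)
    assert len(calls) == 1
    c = calls[0]
    assert (c.position, c.major_allele, c.minor_allele) == (pos, major, minor)
    assert (c.major_count, c.minor_count) == (27, 3)
    assert c.maf == pytest.approx(3 / 30)
    # independent recount at the called column agrees
    assert column_alleles(aln, pos, default_filter) == {major: 27, minor: 3}


def test_triallelic_column_excluded(default_filter):
    rng = np.random.default_rng(6)
    cons = _clean_consensus(rng, 300)
    pos_bi, pos_tri = 100, 200
    minors = [b for b in "ACGT" if b != cons[pos_bi - 1]]
    alts = [b for b in "ACGT" if b != cons[pos_tri - 1]]
    aln = pileup_alignment(cons, depth=30, variants={
        pos_bi: [(minors[0], 3)],
        pos_tri: [(alts[0], 3), (alts[1], 2)],
    })
    assert [c.position for c in call_snps(aln, default_filter)] == [pos_bi]


def test_gap_observation_disqualifies_column(default_filter):
    rng = np.random.default_rng(7)
    cons = _clean_consensus(rng, 300)
    pos = 150
    minor = "A" if cons[pos - 1] != "A" else "G"
    aln = pileup_alignment(cons, depth=30,
                           variants={pos: [(minor, 4), ("-", 1)]})
    assert call_snps(aln, default_filter) == []


def test_minor_allele_or_rule(default_filter):
    """A singleton minor allele passes iff its frequency reaches the MAF floor."""
    rng = np.random.default_rng(8)
    cons = _clean_consensus(rng, 300)
    pos = 150
    minor = "A" if cons[pos - 1] != "A" else "G"
    # depth 50: 1/50 = 0.02 >= 0.01 -> the MAF arm passes a singleton
    aln = pileup_alignment(cons, depth=50, variants={pos: [(minor, 1)]})
    assert len(call_snps(aln, default_filter)) == 1
    # depth 150: 1/150 < 0.01 and count 1 < 2 -> both arms fail
    aln = pileup_alignment(cons, depth=150, variants={pos: [(minor, 1)]})
    assert call_snps(aln, default_filter) == []
    # depth 300, count 2: the minor-read arm passes although MAF is 0.0067
    aln = pileup_alignment(cons, depth=300, variants={pos: [(minor, 2)]})
    assert len(call_snps(aln, default_filter)) == 1


def test_tied_counts_minor_is_lexicographically_later(default_filter):
    rng = np.random.default_rng(9)
    cons = _clean_consensus(rng, 300)
    pos = 150
    aln = pileup_alignment(cons, depth=30,
                           variants={pos: [("T", 15), ("A", 15)]})
    calls = call_snps(aln, default_filter)
    assert len(calls) == 1
    assert calls[0].major_allele == "A" and calls[0].minor_allele == "T"
    assert calls[0].maf == pytest.approx(0.5)


def test_calls_invariant_under_read_reordering(default_filter):
    rng = np.random.default_rng(10)
    cons = _clean_consensus(rng, 300)
    aln = pileup_alignment(cons, depth=30, variants={
        120: [("A" if cons[119] != "A" else "C", 4)],
        210: [("G" if cons[209] != "G" else "C", 5)],
    })
    forward = call_snps(aln, default_filter)
    shuffled = ContigAlignment(aln.contig_id, aln.consensus,
                               aln.consensus_quality,
                               list(reversed(aln.reads)))
    assert call_snps(shuffled, default_filter) == forward
    assert len(forward) == 2


def test_ti_tv_partition_of_calls(default_filter):
    rng = np.random.default_rng(11)
    cons = _clean_consensus(rng, 400)
    variants = {}
    for pos in (100, 170, 240, 310):
        minor = "A" if cons[pos - 1] != "A" else "G"
        variants[pos] = [(minor, 5)]
    aln = pileup_alignment(cons, depth=30, variants=variants)
    calls = call_snps(aln, default_filter)
    assert len(calls) == 4
    n_ti = sum(c.substitution_class == "Ti" for c in calls)
    n_tv = sum(c.substitution_class == "Tv" for c in calls)
    assert n_ti + n_tv == len(calls)


def test_malformed_read_rejected():
    with pytest.raises(ValueError, match="extends past"):
        ContigAlignment("c1", "ACGT", (40,) * 4,
                        [AlignedRead("r0", 2, "GTA", (30, 30, 30))])


def test_pileup_route_matches_alignment_route(default_filter):
    rng = np.random.default_rng(12)
    cons = _clean_consensus(rng, 300)
    pos = 150
    minor = "A" if cons[pos - 1] != "A" else "G"
    aln = pileup_alignment(cons, depth=30, variants={pos: [(minor, 3)]})
    columns = []
    for p in range(1, aln.length + 1):
        bases, quals = [], []
        for r in aln.reads:
            bases.append(r.seq[p - 1])
            quals.append(str(r.qual[p - 1]))
        columns.append(dict(contig_id="c1", pos=p, consensus_base=cons[p - 1],
                            consensus_qual=40, read_bases="".join(bases),
                            read_quals=",".join(quals)))
    assert call_snps_from_pileup(columns, default_filter) == \
        call_snps(aln, default_filter)


# ---------------------------------------------------------------------------
# substitution classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ("A", "G", "Ti"), ("C", "T", "Ti"),
    ("A", "C", "Tv"), ("A", "T", "Tv"), ("C", "G", "Tv"), ("G", "T", "Tv"),
])
def test_substitution_classes(a, b, expected):
    assert classify_substitution(a, b) == expected
    assert classify_substitution(b, a) == expected  # symmetric


@pytest.mark.parametrize("a,b", [("A", "A"), ("A", "N"), ("X", "G")])
def test_substitution_invalid_inputs(a, b):
    with pytest.raises(ValueError):
        classify_substitution(a, b)


# ---------------------------------------------------------------------------
# oracle equivalence on random alignments
# ---------------------------------------------------------------------------

def _random_alignment(rng):
    L = int(rng.integers(25, 51))
    depth = int(rng.integers(8, 16))
    cons = "".join(rng.choice(list("ACGTN"), size=L,
                              p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    cq = rng.integers(15, 45, size=L)
    reads = []
    for i in range(depth):
        start = int(rng.integers(0, max(1, L // 4)))
        end = int(rng.integers(max(start + 1, 3 * L // 4), L + 1))
        seq = list(cons[start:end])
        for j in range(len(seq)):
            u = rng.random()
            if u < 0.08:
                seq[j] = str(rng.choice(list("ACGT")))
            elif u < 0.09:
                seq[j] = "-"
        qual = rng.integers(10, 45, size=end - start)
        reads.append(AlignedRead(f"r{i}", start, "".join(seq),
                                 tuple(int(q) for q in qual)))
    return ContigAlignment("c", cons, tuple(int(q) for q in cq), reads)


def test_caller_matches_brute_force_on_random_alignments(small_filter):
    """Spot-check: the vectorised caller equals a literal per-column rescoring."""
    rng = np.random.default_rng(13)
    cfg = FilterConfig(min_contig_length=20, min_depth=5, flank_len=4,
                       min_base_quality=20, max_homopolymer=3)
    n_with_calls = 0
    for _ in range(100):
        aln = _random_alignment(rng)
        got = [(c.position, c.major_allele, c.minor_allele,
                c.major_count, c.minor_count) for c in call_snps(aln, cfg)]
        assert got == brute_force_calls(aln, cfg)
        n_with_calls += bool(got)
    assert n_with_calls > 10  # the comparison actually exercised calls


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_caller_brute_force_property(seed):
    rng = np.random.default_rng(seed)
    cfg = FilterConfig(min_contig_length=20, min_depth=5, flank_len=4,
                       min_base_quality=20, max_homopolymer=3)
    aln = _random_alignment(rng)
    got = [(c.position, c.major_allele, c.minor_allele,
            c.major_count, c.minor_count) for c in call_snps(aln, cfg)]
    assert got == brute_force_calls(aln, cfg)
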