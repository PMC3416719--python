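import numpy as np
import pytest

from snpfreq.snpcall import AlignedRead, ContigAlignment, FilterConfig


@pytest.fixture
def default_filter() -> FilterConfig:
    return FilterConfig()


@pytest.fixture
def small_filter() -> FilterConfig:
    """Thresholds scaled down for hand-built alignments of a few dozen columns."""
    return FilterConfig(min_contig_length=20, min_depth=5, flank_len=5)


def make_alignment(consensus: str, reads, contig_id: str = "c1",
                   consensus_quality=None) -> ContigAlignment:
    """Build a ContigAlignment from (start, seq, qual) read tuples.

    ``qual`` may be a single int (applied to every base) or a sequence.
    """
    cq = (tuple(consensus_quality) if consensus_quality is not None
          else tuple([40] * len(consensus)))
    out_reads = []
    for i, (start, seq, qual) in enumerate(reads):
        q = tuple([qual] * len(seq)) if isinstance(qual, int) else tuple(qual)
        out_reads.append(AlignedRead(f"r{i}", start, seq, q))
    return ContigAlignment(contig_id, consensus, cq, out_reads)


def pileup_alignment(consensus: str, depth: int, variants=None,
                     quality: int = 35, consensus_quality=None,
                     contig_id: str = "c1") -> ContigAlignment:
    """Full-span reads copying the consensus, with optional per-column edits.

    ``variants`` maps 1-based position -> list of (base, n_reads[, qual]);
    edits are applied to the first reads in order.
    """
    reads = []
    rows = [list(consensus) for _ in range(depth)]
    quals = [[quality] * len(consensus) for _ in range(depth)]
    for pos, edits in (variants or {}).items():
        row = 0
        for edit in edits:
            base, n, *rest = edit
            q = rest[0] if rest else quality
            for _ in range(n):
                rows[row][pos - 1] = base
                quals[row][pos - 1] = q
                row += 1
    for i in range(depth):
        reads.append((0, "".join(rows[i]), quals[i]))
    return make_alignment(consensus, reads, contig_id=contig_id,
                          consensus_quality=consensus_quality)


def random_consensus(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
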