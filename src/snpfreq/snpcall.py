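"""SNP calling on contig alignments via a quality/flank/homopolymer filter cascade.

A contig is the consensus of a set of pyrosequencing reads; candidate SNPs are
columns where quality-passing read bases disagree with each other.  A column is
accepted only if it survives every rule of the cascade:

* the contig is eligible (length and read-depth gates);
* exactly two distinct bases are observed among quality-passing reads, and no
  aligned gap is observed at the column (strict biallelic / indel exclusion);
* the minor allele is frequent enough (MAF >= ``min_maf``) **or** supported by
  enough reads (>= ``min_minor_reads``) — the two criteria combine with OR;
* ``flank_len`` bp of high-quality consensus sequence exist both upstream and
  downstream of the site;
* the site is not inside (or immediately adjacent to) a homopolymer run longer
  than ``max_homopolymer`` bases.

Accepted substitutions are classified as transitions (A<->G, C<->T) or
transversions.  Coordinates are 0-based half-open internally and 1-based in
every output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignedRead",
    "ContigAlignment",
    "FilterConfig",
    "SNPCall",
    "LONG_MIN_CONTIG_LENGTH",
    "eligible_contig",
    "column_alleles",
    "homopolymer_excluded",
    "flank_ok",
    "call_snps",
    "call_snps_from_pileup",
    "classify_substitution",
    "read_alignments",
    "read_pileup_tsv",
    "write_vcf",
    "write_calls_tsv",
]

#: minimum contig length, in bp, of the "long" dataset variant of the caller
LONG_MIN_CONTIG_LENGTH = 501

_BASES = "ACGT"
# byte -> code lookup: A=0 C=1 G=2 T=3 '-'=4 N=5, anything else = 7 (invalid)
_CODE = np.full(256, 7, dtype=np.uint8)
for _i, _b in enumerate("ACGT-N"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_GAP, _N, _ABSENT = 4, 5, 6


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 7).any():
        bad = sorted(set(seq) - set("ACGTacgt-Nn"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    return codes


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """One read placed on a contig consensus.

    ``seq`` is the read as aligned over the consensus: one character per
    consensus column it covers, ``-`` marking a deletion relative to the
    consensus.  ``qual`` holds one Phred-like integer per character of ``seq``
    (values at gap characters are ignored).
    """

    read_id: str
    start: int  # 0-based offset of the first aligned column on the consensus
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"read {self.read_id!r}: negative start {self.start}")
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.seq)} bases but "
                f"{len(self.qual)} quality values"
            )


@dataclass
class ContigAlignment:
    """Consensus sequence (with per-base qualities) plus the reads aligned to it."""

    contig_id: str
    consensus: str
    consensus_quality: tuple[int, ...]
    reads: list[AlignedRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.consensus) < 1:
            raise ValueError(f"{self.contig_id}: empty consensus")
        if len(self.consensus_quality) != len(self.consensus):
            raise ValueError(
                f"{self.contig_id}: consensus length {len(self.consensus)} but "
                f"{len(self.consensus_quality)} quality values"
            )
        for r in self.reads:
            if r.start + len(r.seq) > len(self.consensus):
                raise ValueError(
                    f"{self.contig_id}: read {r.read_id!r} extends past the "
                    f"consensus end ({r.start}+{len(r.seq)} > {len(self.consensus)})"
                )

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def depth(self) -> int:
        """Number of reads aligned to (assembled into) the contig."""
        return len(self.reads)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the SNP-scoring filter cascade.

    ``min_base_quality`` and ``max_homopolymer`` are exclusive thresholds: a
    base passes with quality strictly greater than 20, and runs strictly
    longer than 4 identical bases are excluded.
    """

    min_contig_length: int = 100
    min_depth: int = 10
    min_maf: float = 0.01
    min_minor_reads: int = 2
    flank_len: int = 20
    min_base_quality: int = 20
    max_homopolymer: int = 4

    def __post_init__(self) -> None:
        for name in ("min_contig_length", "min_depth", "min_minor_reads",
                     "flank_len", "min_base_quality", "max_homopolymer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.min_maf <= 0.5:
            raise ValueError(f"min_maf must lie in (0, 0.5], got {self.min_maf}")

    def long_variant(self) -> "FilterConfig":
        """The same cascade restricted to long contigs (>= 501 bp)."""
        return dataclasses.replace(self, min_contig_length=LONG_MIN_CONTIG_LENGTH)


@dataclass(frozen=True)
class SNPCall:
    """One accepted biallelic substitution site."""

    contig_id: str
    position: int  # 1-based on the consensus
    major_allele: str
    minor_allele: str
    major_count: int
    minor_count: int
    maf: float
    substitution_class: str  # "Ti" or "Tv"

    def __post_init__(self) -> None:
        if not (self.major_count >= self.minor_count >= 1):
            raise ValueError("require major_count >= minor_count >= 1")
        if self.major_allele == self.minor_allele:
            raise ValueError("alleles must differ")


# ---------------------------------------------------------------------------
# filter rules
# ---------------------------------------------------------------------------

def classify_substitution(a: str, b: str) -> str:
    """Classify an unordered allele pair as transition ("Ti") or transversion ("Tv")."""
    if a not in _BASES or b not in _BASES:
        raise ValueError(f"alleles must be one of A/C/G/T, got {a!r}, {b!r}")
    if a == b:
        raise ValueError(f"alleles must differ, got {a!r} twice")
    return "Ti" if {a, b} in ({"A", "G"}, {"C", "T"}) else "Tv"


def eligible_contig(alignment: ContigAlignment, cfg: FilterConfig) -> bool:
    """Length and depth gate: >= ``min_contig_length`` bp and >= ``min_depth`` reads."""
    return (alignment.length >= cfg.min_contig_length
            and alignment.depth >= cfg.min_depth)


def column_alleles(alignment: ContigAlignment, position: int,
                   cfg: FilterConfig) -> dict[str, int]:
    """Allele counts at a 1-based column, among quality-passing read bases.

    Bases with quality <= ``min_base_quality`` are ignored entirely; gap
    characters are tallied under key ``"-"`` regardless of quality (they carry
    no quality requirement).  Reads not covering the column contribute nothing.
    Only nonzero counts appear in the result.
    """
    if not 1 <= position <= alignment.length:
        raise IndexError(
            f"position {position} outside contig {alignment.contig_id} "
            f"(length {alignment.length})")
    c = position - 1
    counts: dict[str, int] = {}
    for r in alignment.reads:
        if not r.start <= c < r.start + len(r.seq):
            continue
        base = r.seq[c - r.start].upper()
        if base == "-":
            counts["-"] = counts.get("-", 0) + 1
        elif base in _BASES and r.qual[c - r.start] > cfg.min_base_quality:
            counts[base] = counts.get(base, 0) + 1
    return counts


def _homopolymer_mask(consensus: str, max_homopolymer: int) -> np.ndarray:
    """Boolean mask of columns inside or immediately adjacent to an over-long run."""
    codes = _encode(consensus)
    n = codes.size
    mask = np.zeros(n, dtype=bool)
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))  # half-open run spans
    for s, e in zip(starts, ends):
        if e - s > max_homopolymer and codes[s] < 4:  # only A/C/G/T runs
            mask[max(0, s - 1):min(n, e + 1)] = True
    return mask


def homopolymer_excluded(consensus: str, position: int, cfg: FilterConfig) -> bool:
    """True iff the 1-based position falls in the exclusion zone of a run of
    more than ``max_homopolymer`` identical bases (the run plus one base on
    each side, where homopolymer-driven miscalls concentrate)."""
    if not 1 <= position <= len(consensus):
        raise IndexError(f"position {position} outside consensus of length "
                         f"{len(consensus)}")
    return bool(_homopolymer_mask(consensus, cfg.max_homopolymer)[position - 1])


def _flank_mask(consensus: str, consensus_quality: Sequence[int],
                cfg: FilterConfig) -> np.ndarray:
    """Boolean mask of columns with ``flank_len`` bp of high-quality consensus
    on both sides.  A consensus N never counts as high-quality sequence."""
    codes = _encode(consensus)
    cq = np.asarray(consensus_quality)
    good = ((cq > cfg.min_base_quality) & (codes < 4)).astype(np.int64)
    n = good.size
    f = cfg.flank_len
    ok = np.zeros(n, dtype=bool)
    if n < 2 * f + 1:
        return ok
    csum = np.concatenate(([0], np.cumsum(good)))
    pos = np.arange(f, n - f)
    up = csum[pos] - csum[pos - f]          # columns [pos-f, pos)
    down = csum[pos + f + 1] - csum[pos + 1]  # columns (pos, pos+f]
    ok[pos] = (up == f) & (down == f)
    return ok


def flank_ok(alignment: ContigAlignment, position: int, cfg: FilterConfig) -> bool:
    """True iff ``flank_len`` high-quality consensus bases exist both upstream
    and downstream of the 1-based position."""
    if not 1 <= position <= alignment.length:
        raise IndexError(f"position {position} outside contig "
                         f"{alignment.contig_id} (length {alignment.length})")
    return bool(_flank_mask(alignment.consensus, alignment.consensus_quality,
                            cfg)[position - 1])


# ---------------------------------------------------------------------------
# the caller
# ---------------------------------------------------------------------------

def _column_count_matrix(alignment: ContigAlignment,
                         cfg: FilterConfig) -> tuple[np.ndarray, np.ndarray]:
    """(4, L) quality-passing base counts and (L,) gap counts, vectorised."""
    L = alignment.length
    base_counts = np.zeros((4, L), dtype=np.int64)
    gap_counts = np.zeros(L, dtype=np.int64)
    for r in alignment.reads:
        codes = _encode(r.seq)
        qual = np.asarray(r.qual)
        sl = slice(r.start, r.start + len(r.seq))
        passing = qual > cfg.min_base_quality
        for b in range(4):
            base_counts[b, sl] += (codes == b) & passing
        gap_counts[sl] += codes == _GAP
    return base_counts, gap_counts


def _evaluate_column(contig_id: str, position: int, counts: np.ndarray,
                     n_gaps: int, cfg: FilterConfig) -> SNPCall | None:
    """Apply the allele-level rules (biallelic, indel exclusion, minor-allele
    support) to one column's quality-passing counts.  Flank/homopolymer rules
    are applied by the caller."""
    if n_gaps > 0:
        return None
    present = np.flatnonzero(counts)
    if present.size != 2:
        return None
    i, j = present
    ci, cj = int(counts[i]), int(counts[j])
    if ci > cj:
        major, minor, cmaj, cmin = i, j, ci, cj
    elif cj > ci:
        major, minor, cmaj, cmin = j, i, cj, ci
    else:
        # tie: minor allele is the lexicographically later base
        major, minor, cmaj, cmin = i, j, ci, cj
    maf = cmin / (cmaj + cmin)
    if not (maf >= cfg.min_maf or cmin >= cfg.min_minor_reads):
        return None
    a, b = _BASES[major], _BASES[minor]
    return SNPCall(contig_id=contig_id, position=position, major_allele=a,
                   minor_allele=b, major_count=cmaj, minor_count=cmin,
                   maf=maf, substitution_class=classify_substitution(a, b))


def call_snps(alignment: ContigAlignment, cfg: FilterConfig | None = None,
              ) -> list[SNPCall]:
    """Run the full filter cascade over every column of a contig.

    Returns the accepted calls sorted by position; an ineligible contig
    (too short or too shallow) yields an empty list.
    """
    cfg = cfg or FilterConfig()
    if not eligible_contig(alignment, cfg):
        return []
    base_counts, gap_counts = _column_count_matrix(alignment, cfg)
    flanks = _flank_mask(alignment.consensus, alignment.consensus_quality, cfg)
    homo = _homopolymer_mask(alignment.consensus, cfg.max_homopolymer)
    cons = _encode(alignment.consensus)

    n_alleles = (base_counts > 0).sum(axis=0)
    candidate = (n_alleles == 2) & (gap_counts == 0) & flanks & ~homo & (cons < 4)
    calls = []
    for c in np.flatnonzero(candidate):
        call = _evaluate_column(alignment.contig_id, int(c) + 1,
                                base_counts[:, c], int(gap_counts[c]), cfg)
        if call is not None:
            calls.append(call)
    return calls


def call_snps_from_pileup(columns: Iterable[Mapping], cfg: FilterConfig | None = None,
                          ) -> list[SNPCall]:
    """Run the cascade on pre-tabulated pileup columns of a single contig.

    Each column mapping carries ``contig_id``, ``pos`` (1-based),
    ``consensus_base``, ``consensus_qual``, ``read_bases`` (one character per
    covering read, over ACGTN-) and ``read_quals`` (comma-separated integers,
    aligned with ``read_bases``).  Columns must be contiguous from position 1;
    contig depth is taken as the maximum per-column read count.
    """
    cfg = cfg or FilterConfig()
    cols = sorted(columns, key=lambda r: int(r["pos"]))
    if not cols:
        return []
    ids = {r["contig_id"] for r in cols}
    if len(ids) != 1:
        raise ValueError(f"pileup mixes contigs: {sorted(ids)}")
    contig_id = ids.pop()
    if [int(r["pos"]) for r in cols] != list(range(1, len(cols) + 1)):
        raise ValueError(f"{contig_id}: pileup columns are not contiguous from 1")

    consensus = "".join(str(r["consensus_base"]).upper() for r in cols)
    cq = tuple(int(r["consensus_qual"]) for r in cols)
    depth = max(len(str(r["read_bases"])) for r in cols)
    if len(consensus) < cfg.min_contig_length or depth < cfg.min_depth:
        return []
    flanks = _flank_mask(consensus, cq, cfg)
    homo = _homopolymer_mask(consensus, cfg.max_homopolymer)

    calls = []
    for c, row in enumerate(cols):
        if consensus[c] not in _BASES or not flanks[c] or homo[c]:
            continue
        bases = str(row["read_bases"]).upper()
        quals = [int(q) for q in str(row["read_quals"]).split(",")] if bases else []
        if len(quals) != len(bases):
            raise ValueError(f"{contig_id} pos {c + 1}: {len(bases)} bases but "
                             f"{len(quals)} qualities")
        counts = np.zeros(4, dtype=np.int64)
        n_gaps = 0
        for base, q in zip(bases, quals):
            if base == "-":
                n_gaps += 1
            elif base in _BASES and q > cfg.min_base_quality:
                counts[_BASES.index(base)] += 1
        call = _evaluate_column(contig_id, c + 1, counts, n_gaps, cfg)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# I/O: SAM + FASTA (+QUAL) readers, pileup TSV, VCF/TSV writers
# ---------------------------------------------------------------------------

def _aligned_read_from_sam(rec) -> AlignedRead:
    """Project a SAM record onto consensus columns (M/=/X copy, D -> '-',
    I and S are skipped: inserted bases have no consensus column)."""
    seq_parts: list[str] = []
    qual_parts: list[int] = []
    query = rec.query_sequence or ""
    quals = rec.query_qualities
    if quals is None:
        quals = [0] * len(query)
    qpos = 0
    for op, length in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            seq_parts.append(query[qpos:qpos + length])
            qual_parts.extend(quals[qpos:qpos + length])
            qpos += length
        elif op == 2 or op == 3:  # D, N
            seq_parts.append("-" * length)
            qual_parts.extend([0] * length)
        elif op in (1, 4):  # I, S
            qpos += length
        # H, P consume nothing relevant
    return AlignedRead(read_id=rec.query_name, start=rec.reference_start,
                       seq="".join(seq_parts), qual=tuple(qual_parts))


def read_alignments(sam_path: str | Path, fasta_path: str | Path,
                    qual_path: str | Path | None = None,
                    default_consensus_quality: int = 40,
                    ) -> list[ContigAlignment]:
    """Load contig alignments from a SAM file plus the consensus FASTA.

    ``qual_path`` is an optional FASTA-quality file (space-separated integer
    scores per record); without it every consensus base gets
    ``default_consensus_quality``.
    """
    import pysam
    from Bio import SeqIO

    consensi = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(fasta_path), "fasta")}
    quals: dict[str, tuple[int, ...]] = {}
    if qual_path is not None:
        for rec in SeqIO.parse(str(qual_path), "qual"):
            quals[rec.id] = tuple(rec.letter_annotations["phred_quality"])

    alignments: dict[str, ContigAlignment] = {}
    for cid, seq in consensi.items():
        cq = quals.get(cid, tuple([default_consensus_quality] * len(seq)))
        if len(cq) != len(seq):
            raise ValueError(f"{cid}: consensus has {len(seq)} bp but quality "
                             f"file has {len(cq)} scores")
        alignments[cid] = ContigAlignment(cid, seq, cq, [])

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            if rec.reference_name not in alignments:
                raise ValueError(f"SAM read {rec.query_name!r} maps to "
                                 f"{rec.reference_name!r}, absent from FASTA")
            alignments[rec.reference_name].reads.append(_aligned_read_from_sam(rec))
    out = list(alignments.values())
    for aln in out:  # re-validate read extents against the consensus
        ContigAlignment(aln.contig_id, aln.consensus, aln.consensus_quality,
                        aln.reads)
    return out


def read_pileup_tsv(path: str | Path) -> dict[str, list[dict]]:
    """Read the documented pileup TSV into per-contig column lists."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["contig_id", "pos", "consensus_base", "consensus_qual",
                "read_bases", "read_quals"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pileup TSV missing columns: {missing}")
    out: dict[str, list[dict]] = {}
    for row in df.to_dict("records"):
        out.setdefault(row["contig_id"], []).append(row)
    return out


def write_vcf(calls: Sequence[SNPCall], path: str | Path) -> None:
    """Write calls as minimal VCF 4.2 (REF = major allele, ALT = minor)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=snpfreq",
        '##INFO=<ID=MAJC,Number=1,Type=Integer,Description="Major allele read count">',
        '##INFO=<ID=MINC,Number=1,Type=Integer,Description="Minor allele read count">',
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Substitution class (Ti/Tv)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        info = (f"MAJC={c.major_count};MINC={c.minor_count};"
                f"MAF={c.maf:.6g};CLASS={c.substitution_class}")
        lines.append(f"{c.contig_id}\t{c.position}\t.\t{c.major_allele}\t"
                     f"{c.minor_allele}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_calls_tsv(calls: Sequence[SNPCall], path: str | Path) -> None:
    """Flat TSV mirror of the VCF output."""
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(c) for c in calls],
                 columns=[f.name for f in dataclasses.fields(SNPCall)],
                 ).to_csv(path, sep="\t", index=False)
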