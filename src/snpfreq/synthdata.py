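"""Synthetic contig alignments and per-contig SNP count tables.

Two generators stand in for a 454 transcriptome run:

``simulate_alignments``
    builds contig consensus sequences with full-span reads, plants biallelic
    SNPs at controlled minor-allele counts, and plants one decoy class per
    filter rule of the SNP-scoring cascade (homopolymer runs, read-level
    indels, triallelic columns, singleton minor alleles below the MAF floor,
    sites near contig ends, low-quality flanks).  A truth table enumerates
    every planted event so that caller recall and precision can be measured
    exactly.

``simulate_count_table``
    draws per-contig SNP counts from a negative-binomial (NB2) regression with
    log link, log mu = b0 + bL*length + bD*depth + bC*coding, the generating
    model of the downstream regression fits.

Contig length and depth distributions are truncated lognormals calibrated so
that their truncated means and ranges match a typical 454 transcriptome
assembly (mean length ~811 bp over 100-5,400 bp; mean depth ~28 reads over
10-315).  Both generators derive one independent RNG substream per contig from
the root seed, so contig i is reproducible regardless of ``n_contigs``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .snpcall import AlignedRead, ContigAlignment, FilterConfig, _BASES

__all__ = [
    "Dist",
    "AlignmentSimConfig",
    "CountSimConfig",
    "TruthTable",
    "simulate_alignments",
    "simulate_count_table",
    "write_fasta",
    "write_qual",
    "write_sam",
    "write_truth_tsv",
    "write_count_table_tsv",
    "read_count_table_tsv",
    "read_flat_config",
    "LENGTH_DIST_ALL",
    "LENGTH_DIST_LONG",
    "DEPTH_DIST_ALL",
    "DEPTH_DIST_LONG",
]


class ConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


# ---------------------------------------------------------------------------
# named distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dist:
    """A named sampling distribution with keyword parameters.

    Supported names:

    * ``lognormal_trunc(mu, sigma, low, high[, shift])`` — ``shift`` +
      lognormal, rejection-truncated to [low, high];
    * ``uniform(low, high)`` — continuous;
    * ``uniform_int(low, high)`` — integers, both ends inclusive;
    * ``constant(value)``.
    """

    name: str
    params: tuple[tuple[str, float], ...]

    @classmethod
    def make(cls, name: str, **params: float) -> "Dist":
        return cls(name, tuple(sorted(params.items())))

    def _p(self) -> dict[str, float]:
        return dict(self.params)

    def validate(self, field_name: str) -> None:
        p = self._p()
        try:
            if self.name == "lognormal_trunc":
                if p["sigma"] <= 0:
                    raise ValueError("sigma must be > 0")
                if p["low"] >= p["high"]:
                    raise ValueError("low must be < high")
                p.setdefault("shift", 0.0)
            elif self.name in ("uniform", "uniform_int"):
                if p["low"] > p["high"]:
                    raise ValueError("low must be <= high")
            elif self.name == "constant":
                p["value"]
            else:
                raise ValueError(f"unknown distribution {self.name!r}")
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{field_name}: invalid distribution "
                              f"{self.name}({dict(self.params)}): {exc}") from exc

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self._p()
        if self.name == "lognormal_trunc":
            shift = p.get("shift", 0.0)
            out = np.empty(size)
            n = 0
            while n < size:
                x = shift + rng.lognormal(p["mu"], p["sigma"], size)
                x = x[(x >= p["low"]) & (x <= p["high"])]
                take = min(size - n, x.size)
                out[n:n + take] = x[:take]
                n += take
            return out
        if self.name == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.name == "uniform_int":
            return rng.integers(int(p["low"]), int(p["high"]) + 1, size).astype(float)
        if self.name == "constant":
            return np.full(size, p["value"])
        raise ConfigError(f"unknown distribution {self.name!r}")


# truncated-lognormal parameters calibrated to the target truncated means
LENGTH_DIST_ALL = Dist.make("lognormal_trunc", mu=6.424, sigma=0.75,
                            low=100, high=5400)          # mean ~811 bp
LENGTH_DIST_LONG = Dist.make("lognormal_trunc", mu=6.591, sigma=0.55,
                             low=501, high=5354)         # mean ~1003 bp
DEPTH_DIST_ALL = Dist.make("lognormal_trunc", mu=2.543, sigma=0.9,
                           shift=9, low=10, high=315)    # mean ~28 reads
DEPTH_DIST_LONG = Dist.make("lognormal_trunc", mu=2.736, sigma=0.9,
                            shift=9, low=10, high=315)   # mean ~32 reads


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentSimConfig:
    """Controls for the read-level alignment simulator.

    Decoy rates are expected events per contig (Poisson).  The low-minor decoy
    (one supporting read at MAF < 0.01) is only realisable at site depth above
    1/MAF, so contigs receiving one are forced to depth >= 150.
    """

    n_contigs: int = 100
    length_dist: Dist = LENGTH_DIST_ALL
    depth_dist: Dist = DEPTH_DIST_ALL
    prop_coding: float = 0.47        # coding fraction of an all-contig dataset
    snp_rate_per_kb: float = 0.81    # ~0.65 SNPs per mean-length contig
    minor_freq_dist: Dist = Dist.make("uniform", low=0.08, high=0.5)
    ti_proportion: float = 0.64      # transition share of planted substitutions
    base_error_rate: float = 0.001
    quality_dist: Dist = Dist.make("uniform_int", low=25, high=40)
    error_quality_dist: Dist = Dist.make("uniform_int", low=5, high=20)
    homopolymer_decoy_rate: float = 0.05
    indel_decoy_rate: float = 0.05
    triallelic_decoy_rate: float = 0.05
    low_minor_decoy_rate: float = 0.05
    edge_decoy_rate: float = 0.05
    lowqual_flank_decoy_rate: float = 0.05
    full_span_reads: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ConfigError(f"n_contigs: must be >= 1, got {self.n_contigs}")
        if not 0.0 <= self.prop_coding <= 1.0:
            raise ConfigError(f"prop_coding: must lie in [0, 1], "
                              f"got {self.prop_coding}")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ConfigError(f"base_error_rate: must lie in [0, 1], "
                              f"got {self.base_error_rate}")
        for name in ("snp_rate_per_kb", "homopolymer_decoy_rate",
                     "indel_decoy_rate", "triallelic_decoy_rate",
                     "low_minor_decoy_rate", "edge_decoy_rate",
                     "lowqual_flank_decoy_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0, "
                                  f"got {getattr(self, name)}")
        if not 0.0 <= self.ti_proportion <= 1.0:
            raise ConfigError(f"ti_proportion: must lie in [0, 1], "
                              f"got {self.ti_proportion}")
        for name in ("length_dist", "depth_dist", "minor_freq_dist",
                     "quality_dist", "error_quality_dist"):
            getattr(self, name).validate(name)


@dataclass(frozen=True)
class CountSimConfig:
    """Controls for the NB2 per-contig count simulator.

    ``true_beta`` is (intercept, length, depth, coding-indicator) on the
    log-link scale; ``dispersion_alpha`` is the NB2 dispersion (variance
    mu + alpha*mu^2; 0 gives the Poisson limit).  Defaults emulate a long
    (>= 501 bp) contig dataset.
    """

    n_contigs: int = 3181
    true_beta: tuple[float, float, float, float] = (-0.9828, 0.0002,
                                                    0.0146, -0.0999)
    dispersion_alpha: float = 0.5
    length_dist: Dist = LENGTH_DIST_LONG
    depth_dist: Dist = DEPTH_DIST_LONG
    prop_coding: float = 0.554       # coding fraction of a long-contig dataset
    ti_proportion: float = 0.64      # Ti/(Ti+Tv) at Ti/Tv ~ 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ConfigError(f"n_contigs: must be >= 1, got {self.n_contigs}")
        if len(self.true_beta) != 4:
            raise ConfigError(f"true_beta: need 4 coefficients, "
                              f"got {len(self.true_beta)}")
        if self.dispersion_alpha < 0:
            raise ConfigError(f"dispersion_alpha: must be >= 0, "
                              f"got {self.dispersion_alpha}")
        if not 0.0 <= self.prop_coding <= 1.0:
            raise ConfigError(f"prop_coding: must lie in [0, 1], "
                              f"got {self.prop_coding}")
        if not 0.0 <= self.ti_proportion <= 1.0:
            raise ConfigError(f"ti_proportion: must lie in [0, 1], "
                              f"got {self.ti_proportion}")
        for name in ("length_dist", "depth_dist"):
            getattr(self, name).validate(name)


@dataclass
class TruthTable:
    """Planted events: one row per true SNP, one per decoy.

    ``variants`` columns: contig_id, position (1-based), major_allele,
    minor_allele, minor_count.  ``decoys`` columns: contig_id, position, kind
    (homopolymer | indel | triallelic | low_minor | edge | lowqual_flank).
    """

    variants: pd.DataFrame
    decoys: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)  # contig_id -> coding/noncoding


DECOY_KINDS = ("homopolymer", "indel", "triallelic", "low_minor", "edge",
               "lowqual_flank")


# ---------------------------------------------------------------------------
# alignment simulation
# ---------------------------------------------------------------------------

def _contig_rng(seed: int, index: int) -> np.random.Generator:
    # per-contig substream: reproducible independently of n_contigs
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _other_bases(rng: np.random.Generator, base_codes: np.ndarray) -> np.ndarray:
    """Uniformly draw a base code different from each given code."""
    shift = rng.integers(1, 4, size=base_codes.shape)
    return (base_codes + shift) % 4


def _pick_positions(rng: np.random.Generator, eligible: np.ndarray, n: int,
                    reserved: list[int], min_sep: int) -> list[int]:
    """Draw up to n eligible 0-based positions, each >= min_sep from all
    previously reserved positions."""
    chosen: list[int] = []
    candidates = np.flatnonzero(eligible)
    if candidates.size == 0:
        return chosen
    order = rng.permutation(candidates.size)
    for idx in order:
        if len(chosen) == n:
            break
        p = int(candidates[idx])
        if all(abs(p - q) >= min_sep for q in reserved):
            chosen.append(p)
            reserved.append(p)
    return chosen


def simulate_alignments(config: AlignmentSimConfig,
                        filter_config: FilterConfig | None = None,
                        ) -> tuple[list[ContigAlignment], TruthTable]:
    """Generate contig alignments with planted SNPs and per-filter-rule decoys.

    Planted SNPs are placed only at sites that pass every rule of
    ``filter_config`` (mid-contig, high-quality flanks, outside homopolymer
    exclusion zones) with minor-allele support of at least
    ``filter_config.min_minor_reads`` reads, so on an error-free run the truth
    table is exactly the set of callable sites.  Each decoy class violates
    exactly one rule.  Events are spaced so they cannot interact.
    """
    cfg = config
    fcfg = filter_config or FilterConfig()
    run = fcfg.max_homopolymer + 1  # shortest excluded homopolymer run
    min_sep = 2 * fcfg.flank_len + run + 3

    alignments: list[ContigAlignment] = []
    var_rows: list[dict] = []
    decoy_rows: list[dict] = []
    labels: dict[str, str] = {}

    for i in range(cfg.n_contigs):
        rng = _contig_rng(cfg.seed, i)
        cid = f"contig{i:05d}"
        L = int(round(cfg.length_dist.sample(rng, 1)[0]))
        D = int(round(cfg.depth_dist.sample(rng, 1)[0]))
        coding = bool(rng.random() < cfg.prop_coding)
        labels[cid] = "coding" if coding else "noncoding"

        n_snp = int(rng.poisson(cfg.snp_rate_per_kb * L / 1000.0))
        n_decoy = {k: int(rng.poisson(getattr(cfg, f"{k}_decoy_rate")))
                   for k in ("homopolymer", "indel", "triallelic", "low_minor",
                             "edge", "lowqual_flank")}
        if n_decoy["low_minor"] > 0:
            D = max(D, 150)  # singleton below MAF 0.01 needs depth > 100

        cons_codes = rng.integers(0, 4, size=L)
        cons_qual = cfg.quality_dist.sample(rng, L).astype(int)

        # interior positions with full flanks; homopolymer zones handled below
        interior = np.zeros(L, dtype=bool)
        if L >= 2 * fcfg.flank_len + 1:
            interior[fcfg.flank_len:L - fcfg.flank_len] = True
        # natural homopolymer exclusion zones of the raw consensus
        homo = _natural_homopolymer_zones(cons_codes, fcfg.max_homopolymer)
        lowq = cons_qual <= fcfg.min_base_quality
        # a site is plantable if its column and whole flank window are clean
        clean = ~(homo | lowq)
        window_ok = _all_in_window(clean, fcfg.flank_len)
        eligible = interior & window_ok

        reserved: list[int] = []
        snp_pos = _pick_positions(rng, eligible, n_snp, reserved, min_sep)
        homo_pos = _pick_positions(rng, eligible, n_decoy["homopolymer"],
                                   reserved, min_sep)
        indel_pos = _pick_positions(rng, eligible, n_decoy["indel"],
                                    reserved, min_sep)
        tri_pos = _pick_positions(rng, eligible, n_decoy["triallelic"],
                                  reserved, min_sep)
        lowminor_pos = _pick_positions(rng, eligible, n_decoy["low_minor"],
                                       reserved, min_sep)
        lowqf_pos = _pick_positions(rng, eligible, n_decoy["lowqual_flank"],
                                    reserved, min_sep)
        # edge decoys live where the flank rule fails by construction
        edge_eligible = np.zeros(L, dtype=bool)
        edge_n = min(fcfg.flank_len, L)
        edge_eligible[:edge_n] = True
        edge_eligible[L - edge_n:] = True
        edge_eligible &= ~(homo | lowq)
        edge_pos = _pick_positions(rng, edge_eligible, n_decoy["edge"],
                                   reserved, min_sep)

        # consensus modifications: homopolymer runs and flank-quality dips
        for p in homo_pos:
            cons_codes[p:p + run] = cons_codes[p]
        for p in lowqf_pos:
            cons_qual[p + rng.integers(1, fcfg.flank_len + 1)] = 10

        consensus = "".join(_BASES[c] for c in cons_codes)

        # read matrix: full-span copies of the consensus plus sequencing error.
        # Miscalled bases carry low quality scores (pyrosequencing errors are
        # predominantly low-confidence), so the >min_base_quality filter is
        # what removes them downstream.
        read_codes = np.tile(cons_codes, (D, 1))
        read_qual = cfg.quality_dist.sample(rng, D * L).astype(int).reshape(D, L)
        if cfg.base_error_rate > 0:
            err = rng.random((D, L)) < cfg.base_error_rate
            read_codes[err] = _other_bases(rng, read_codes[err])
            read_qual[err] = cfg.error_quality_dist.sample(
                rng, int(err.sum())).astype(int)
        gap_mask = np.zeros((D, L), dtype=bool)

        def draw_alt(major: int, exclude: list[int]) -> int:
            # transition partner with probability ti_proportion, else one of
            # the two transversion partners (Ti/Tv ~ 1.8 at the 0.64 default)
            ti = (major + 2) % 4
            tvs = [b for b in range(4) if b != major and b != ti]
            while True:
                if rng.random() < cfg.ti_proportion:
                    alt = ti
                else:
                    alt = int(tvs[rng.integers(0, 2)])
                if alt not in exclude:
                    return alt

        def plant(p: int, minor_count: int, n_alleles: int = 1) -> tuple[str, list[str]]:
            """Overwrite minor_count reads per alternate allele at column p."""
            major = int(cons_codes[p])
            alts: list[int] = []
            pool = rng.permutation(D)
            taken = 0
            for _ in range(n_alleles):
                alt = draw_alt(major, alts)
                alts.append(alt)
                rows = pool[taken:taken + minor_count]
                taken += minor_count
                read_codes[rows, p] = alt
                read_qual[rows, p] = int(cfg.quality_dist.sample(rng, 1)[0])
            # restore the majority so sequencing error cannot add a 3rd allele
            rest = pool[taken:]
            read_codes[rest, p] = major
            return _BASES[major], [_BASES[a] for a in alts]

        def planted_minor_count() -> int:
            f = float(cfg.minor_freq_dist.sample(rng, 1)[0])
            return int(np.clip(round(f * D), fcfg.min_minor_reads, D // 2))

        for p in snp_pos:
            m = planted_minor_count()
            major, (minor,) = plant(p, m)
            var_rows.append(dict(contig_id=cid, position=p + 1,
                                 major_allele=major, minor_allele=minor,
                                 minor_count=m))
        for p, kind in [(q, "homopolymer") for q in homo_pos] + \
                       [(q, "edge") for q in edge_pos] + \
                       [(q, "lowqual_flank") for q in lowqf_pos]:
            plant(p, planted_minor_count())
            decoy_rows.append(dict(contig_id=cid, position=p + 1, kind=kind))
        for p in tri_pos:
            plant(p, max(planted_minor_count() // 2, fcfg.min_minor_reads),
                  n_alleles=2)
            decoy_rows.append(dict(contig_id=cid, position=p + 1,
                                   kind="triallelic"))
        for p in lowminor_pos:
            plant(p, 1)
            decoy_rows.append(dict(contig_id=cid, position=p + 1,
                                   kind="low_minor"))
        for p in indel_pos:
            plant(p, planted_minor_count())
            rows = rng.choice(D, size=max(1, D // 10), replace=False)
            gap_mask[rows, p] = True
            decoy_rows.append(dict(contig_id=cid, position=p + 1, kind="indel"))

        # read span boundaries
        if cfg.full_span_reads:
            starts = np.zeros(D, dtype=int)
            ends = np.full(D, L, dtype=int)
        else:
            starts = rng.integers(0, max(1, L // 4), size=D)
            ends = L - rng.integers(0, max(1, L // 4), size=D)
            ends = np.maximum(ends, starts + 1)

        reads = []
        for j in range(D):
            s, e = int(starts[j]), int(ends[j])
            chars = np.array(list(_BASES + "-"))[
                np.where(gap_mask[j, s:e], 4, read_codes[j, s:e])]
            reads.append(AlignedRead(
                read_id=f"{cid}.r{j:04d}", start=s, seq="".join(chars),
                qual=tuple(int(q) for q in read_qual[j, s:e])))

        alignments.append(ContigAlignment(
            contig_id=cid, consensus=consensus,
            consensus_quality=tuple(int(q) for q in cons_qual), reads=reads))

    variants = pd.DataFrame(
        var_rows, columns=["contig_id", "position", "major_allele",
                           "minor_allele", "minor_count"])
    decoys = pd.DataFrame(decoy_rows, columns=["contig_id", "position", "kind"])
    return alignments, TruthTable(variants=variants, decoys=decoys, labels=labels)


def _natural_homopolymer_zones(codes: np.ndarray, max_run: int) -> np.ndarray:
    """Exclusion zones (run + adjacent base each side) of runs longer than
    max_run, plus a one-run margin so later consensus edits cannot create a
    new over-long run across an event site."""
    n = codes.size
    mask = np.zeros(n, dtype=bool)
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for s, e in zip(starts, ends):
        if e - s >= max_run:  # margin: runs of exactly max_run also avoided
            mask[max(0, s - 2):min(n, e + 2)] = True
    return mask


def _all_in_window(clean: np.ndarray, flank: int) -> np.ndarray:
    """True where every column within +-flank (inclusive) is clean."""
    n = clean.size
    csum = np.concatenate(([0], np.cumsum(clean.astype(np.int64))))
    out = np.zeros(n, dtype=bool)
    for p in range(n):
        lo, hi = max(0, p - flank), min(n, p + flank + 1)
        out[p] = (csum[hi] - csum[lo]) == (hi - lo)
    return out


# ---------------------------------------------------------------------------
# count-table simulation
# ---------------------------------------------------------------------------

def simulate_count_table(config: CountSimConfig) -> pd.DataFrame:
    """Draw a per-contig count table from the NB2 generating model.

    Returns a DataFrame with columns ``contig_id length depth cnc n_snp n_ti
    n_tv``; transitions are a binomial split of each contig's SNP count at
    ``ti_proportion``.
    """
    cfg = config
    rng = _contig_rng(cfg.seed, 0)
    n = cfg.n_contigs
    length = np.round(cfg.length_dist.sample(rng, n)).astype(int)
    depth = np.round(cfg.depth_dist.sample(rng, n)).astype(int)
    cnc = (rng.random(n) < cfg.prop_coding).astype(int)
    b0, bl, bd, bc = cfg.true_beta
    mu = np.exp(b0 + bl * length + bd * depth + bc * cnc)
    if not np.all(np.isfinite(mu)):
        raise ConfigError("true_beta: non-finite NB mean for simulated covariates")
    if cfg.dispersion_alpha > 0:
        lam = rng.gamma(shape=1.0 / cfg.dispersion_alpha,
                        scale=cfg.dispersion_alpha * mu)
        n_snp = rng.poisson(lam)
    else:
        n_snp = rng.poisson(mu)
    n_ti = rng.binomial(n_snp, cfg.ti_proportion)
    return pd.DataFrame({
        "contig_id": [f"contig{i:05d}" for i in range(n)],
        "length": length, "depth": depth, "cnc": cnc,
        "n_snp": n_snp, "n_ti": n_ti, "n_tv": n_snp - n_ti,
    })


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_fasta(alignments: list[ContigAlignment], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(a.consensus), id=a.contig_id, description="")
               for a in alignments]
    SeqIO.write(records, str(path), "fasta")


def write_qual(alignments: list[ContigAlignment], path: str | Path) -> None:
    """FASTA-quality dialect: per-record space-separated integer scores."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f">{a.contig_id}\n")
            fh.write(" ".join(str(q) for q in a.consensus_quality) + "\n")


def write_sam(alignments: list[ContigAlignment], path: str | Path) -> None:
    """One reference per contig; reads carry per-base qualities in QUAL.
    Gap characters in aligned reads become CIGAR deletions."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": a.contig_id, "LN": a.length} for a in alignments]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for tid, a in enumerate(alignments):
            for r in a.reads:
                rec = pysam.AlignedSegment()
                rec.query_name = r.read_id
                rec.reference_id = tid
                rec.reference_start = r.start
                rec.mapping_quality = 60
                rec.flag = 0
                seq = r.seq.replace("-", "")
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(min(q, 93) + 33)
                            for q, b in zip(r.qual, r.seq) if b != "-"))
                rec.cigartuples = _cigar_from_aligned(r.seq)
                out.write(rec)


def _cigar_from_aligned(seq: str) -> list[tuple[int, int]]:
    ops = []
    for ch in seq:
        op = 2 if ch == "-" else 0  # D or M
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return ops


def write_truth_tsv(truth: TruthTable, variants_path: str | Path,
                    decoys_path: str | Path,
                    labels_path: str | Path | None = None) -> None:
    truth.variants.to_csv(variants_path, sep="\t", index=False)
    truth.decoys.to_csv(decoys_path, sep="\t", index=False)
    if labels_path is not None:
        pd.DataFrame(sorted(truth.labels.items()),
                     columns=["contig_id", "class"]
                     ).to_csv(labels_path, sep="\t", index=False)


def write_count_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_count_table_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["contig_id", "length", "depth", "cnc", "n_snp", "n_ti", "n_tv"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# flat key-value configuration files
# ---------------------------------------------------------------------------

_SIM_FIELDS = {f.name: f for f in dataclasses.fields(AlignmentSimConfig)}
_COUNT_FIELDS = {f.name: f for f in dataclasses.fields(CountSimConfig)}


def _parse_dist(value: str, field_name: str) -> Dist:
    """Parse e.g. ``lognormal_trunc(mu=6.4, sigma=0.75, low=100, high=5400)``."""
    value = value.strip()
    if "(" not in value or not value.endswith(")"):
        raise ConfigError(f"{field_name}: cannot parse distribution {value!r}")
    name, _, body = value.partition("(")
    params = {}
    body = body[:-1].strip()
    if body:
        for part in body.split(","):
            if "=" not in part:
                raise ConfigError(f"{field_name}: cannot parse distribution "
                                  f"parameter {part.strip()!r}")
            k, _, v = part.partition("=")
            params[k.strip()] = float(v)
    dist = Dist.make(name.strip(), **params)
    dist.validate(field_name)
    return dist


def _coerce(field_obj: dataclasses.Field, raw: str, name: str):
    if field_obj.type in ("Dist",):
        return _parse_dist(raw, name)
    raw = raw.strip()
    if field_obj.type == "bool":
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"{name}: expected a boolean, got {raw!r}")
    if field_obj.type == "int":
        return int(raw)
    if field_obj.type == "float":
        return float(raw)
    if field_obj.type.startswith("tuple"):
        return tuple(float(x) for x in raw.split(","))
    return raw


def read_flat_config(path: str | Path) -> dict[str, object]:
    """Parse a flat ``key = value`` config file covering both simulator
    configs.  Keys may be prefixed ``alignment.`` or ``counts.``; unknown keys
    raise :class:`ConfigError`.  Returns a dict with any of the keys
    ``alignment`` (AlignmentSimConfig kwargs) and ``counts`` (CountSimConfig
    kwargs), plus top-level scalars (e.g. ``seed``).
    """
    out: dict[str, object] = {"alignment": {}, "counts": {}}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key.startswith("alignment."):
            name = key[len("alignment."):]
            if name not in _SIM_FIELDS:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            out["alignment"][name] = _coerce(_SIM_FIELDS[name], raw, key)
        elif key.startswith("counts."):
            name = key[len("counts."):]
            if name not in _COUNT_FIELDS:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            out["counts"][name] = _coerce(_COUNT_FIELDS[name], raw, key)
        elif key == "seed":
            out["seed"] = int(raw)
        else:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
    return out
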