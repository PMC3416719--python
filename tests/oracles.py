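"""Independent reference implementations used only to cross-check the package.

These share no code with snpfreq: the SNP scorer below is a literal,
unoptimised per-column transcription of the filter rules, and the NB2
log-likelihood is evaluated directly from gamma functions.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def brute_force_calls(alignment, cfg) -> list[tuple]:
    """Plain per-column rescoring; returns (position, major, minor, nmaj, nmin)."""
    L = len(alignment.consensus)
    if L < cfg.min_contig_length or len(alignment.reads) < cfg.min_depth:
        return []

    # maximal homopolymer runs of the consensus, as (start, end) half-open
    runs = []
    i = 0
    while i < L:
        j = i
        while j < L and alignment.consensus[j] == alignment.consensus[i]:
            j += 1
        runs.append((i, j, alignment.consensus[i]))
        i = j

    calls = []
    for pos in range(1, L + 1):
        c = pos - 1
        if alignment.consensus[c] not in "ACGT":
            continue
        counts: dict[str, int] = {}
        gaps = 0
        for r in alignment.reads:
            idx = c - r.start
            if not 0 <= idx < len(r.seq):
                continue
            ch = r.seq[idx].upper()
            if ch == "-":
                gaps += 1
            elif ch in "ACGT" and r.qual[idx] > cfg.min_base_quality:
                counts[ch] = counts.get(ch, 0) + 1
        if gaps > 0 or len(counts) != 2:
            continue
        (a, na), (b, nb) = sorted(counts.items())
        if na >= nb:  # tie: minor is the lexicographically later base
            major, minor, cmaj, cmin = a, b, na, nb
        else:
            major, minor, cmaj, cmin = b, a, nb, na
        maf = cmin / (cmaj + cmin)
        if not (maf >= cfg.min_maf or cmin >= cfg.min_minor_reads):
            continue
        if c - cfg.flank_len < 0 or c + cfg.flank_len > L - 1:
            continue
        flank_cols = list(range(c - cfg.flank_len, c)) + \
            list(range(c + 1, c + cfg.flank_len + 1))
        if any(alignment.consensus[j] not in "ACGT"
               or alignment.consensus_quality[j] <= cfg.min_base_quality
               for j in flank_cols):
            continue
        in_homopolymer = any(
            s - 1 <= c <= e and base in "ACGT"
            for s, e, base in runs if e - s > cfg.max_homopolymer)
        if in_homopolymer:
            continue
        calls.append((pos, major, minor, cmaj, cmin))
    return calls


def nb2_loglik(y, X, beta, alpha) -> float:
    """Direct NB2 log-likelihood: y ~ NegBin(mu = exp(X beta), Var = mu + alpha mu^2)."""
    y = np.asarray(y, dtype=float)
    mu = np.exp(np.asarray(X) @ np.asarray(beta))
    r = 1.0 / alpha
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


def pearson_textbook(x, y) -> float:
    """Sample Pearson correlation from the definitional formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx ** 2).sum() * (dy ** 2).sum()))
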