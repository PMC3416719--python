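"""Per-contig regression table: joins, subsets, summaries and correlations.

One row per eligible contig: its length in bp, its depth (the number of reads
assembled into it), a coding indicator (1 = protein-coding transcript,
0 = non-coding) and its SNP / transition / transversion counts.  This table
is both the summary-statistics surface (dataset totals, Ti/Tv ratios,
length- and depth-correlations) and the input to the negative-binomial
regression models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .snpcall import SNPCall

__all__ = [
    "RECORD_COLUMNS",
    "DatasetSummary",
    "build_table",
    "subset_long",
    "summarize",
    "titv_ratio",
    "pearson",
    "read_labels_tsv",
]

RECORD_COLUMNS = ["contig_id", "length", "depth", "cnc", "n_snp", "n_ti", "n_tv"]

_CODING = {"coding": 1, "noncoding": 0, "1": 1, "0": 0}


@dataclass(frozen=True)
class ClassSummary:
    n_contigs: int
    mean_length: float
    mean_depth: float
    total_snp: int
    total_ti: int
    total_tv: int


@dataclass(frozen=True)
class DatasetSummary:
    """Dataset totals and means, overall and split by coding class."""

    overall: ClassSummary
    coding: ClassSummary
    noncoding: ClassSummary


def _coding_code(label: str) -> int:
    key = str(label).strip().lower()
    if key not in _CODING:
        raise ValueError(f"unrecognised coding label {label!r} "
                         f"(expected coding/noncoding or 1/0)")
    return _CODING[key]


def build_table(calls: Sequence[SNPCall],
                contig_meta: Mapping[str, tuple[int, int]],
                labels: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate SNP calls into one record per contig.

    ``contig_meta`` maps contig_id -> (length, depth) for every eligible
    contig; contigs with no calls still get zero-count rows.  Every contig
    needs a label in ``labels`` (coding/noncoding, or 1/0).
    """
    unlabeled = sorted(set(contig_meta) - set(labels))
    if unlabeled:
        raise ValueError(f"contigs missing a coding/non-coding label: "
                         f"{unlabeled[:10]}{'...' if len(unlabeled) > 10 else ''}")
    stray = sorted({c.contig_id for c in calls} - set(contig_meta))
    if stray:
        raise ValueError(f"calls reference contigs absent from metadata: "
                         f"{stray[:10]}{'...' if len(stray) > 10 else ''}")

    n_ti: dict[str, int] = {cid: 0 for cid in contig_meta}
    n_tv: dict[str, int] = {cid: 0 for cid in contig_meta}
    for c in calls:
        if c.substitution_class == "Ti":
            n_ti[c.contig_id] += 1
        else:
            n_tv[c.contig_id] += 1
    rows = [{
        "contig_id": cid, "length": meta[0], "depth": meta[1],
        "cnc": _coding_code(labels[cid]),
        "n_snp": n_ti[cid] + n_tv[cid], "n_ti": n_ti[cid], "n_tv": n_tv[cid],
    } for cid, meta in contig_meta.items()]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def subset_long(records: pd.DataFrame, min_length: int = 501) -> pd.DataFrame:
    """Restrict the table to long contigs (length >= ``min_length`` bp)."""
    return records[records["length"] >= min_length].reset_index(drop=True)


def _class_summary(df: pd.DataFrame) -> ClassSummary:
    if len(df) == 0:
        return ClassSummary(0, float("nan"), float("nan"), 0, 0, 0)
    return ClassSummary(
        n_contigs=len(df),
        mean_length=float(df["length"].mean()),
        mean_depth=float(df["depth"].mean()),
        total_snp=int(df["n_snp"].sum()),
        total_ti=int(df["n_ti"].sum()),
        total_tv=int(df["n_tv"].sum()),
    )


def summarize(records: pd.DataFrame) -> DatasetSummary:
    """Dataset totals and arithmetic means, overall and per coding class."""
    if len(records) == 0:
        raise ValueError("cannot summarise an empty contig table")
    return DatasetSummary(
        overall=_class_summary(records),
        coding=_class_summary(records[records["cnc"] == 1]),
        noncoding=_class_summary(records[records["cnc"] == 0]),
    )


def titv_ratio(n_ti: int, n_tv: int) -> float:
    """Transition/transversion ratio Ti/Tv."""
    if n_tv == 0:
        raise ZeroDivisionError("Ti/Tv undefined: zero transversions")
    return n_ti / n_tv


def pearson(records: pd.DataFrame, x: str, y: str,
            cnc: int | None = None) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between a covariate and a count.

    ``x`` is ``length`` or ``depth``; ``y`` one of ``n_snp``/``n_ti``/``n_tv``;
    ``cnc`` optionally restricts to one coding class.  The p-value is the
    usual t-distribution test on r.
    """
    if x not in ("length", "depth"):
        raise ValueError(f"x must be 'length' or 'depth', got {x!r}")
    if y not in ("n_snp", "n_ti", "n_tv"):
        raise ValueError(f"y must be one of n_snp/n_ti/n_tv, got {y!r}")
    df = records if cnc is None else records[records["cnc"] == cnc]
    if len(df) < 3:
        raise ValueError(f"need at least 3 records, have {len(df)}")
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise ValueError(f"degenerate input: zero variance in {x if np.var(xv) == 0 else y}")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


def read_labels_tsv(path) -> dict[str, str]:
    """Read a labels TSV ``contig_id  class  [score]`` into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("contig_id", "class"):
        if col not in df.columns:
            raise ValueError(f"labels TSV missing column {col!r}")
    return dict(zip(df["contig_id"], df["class"]))
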