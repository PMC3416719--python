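"""One-command orchestration: simulate -> call -> table -> fit -> report.

A :class:`RunConfig` (parsed from a flat ``key = value`` file) drives the
stages; every output directory gets a ``manifest.json`` recording the config
hash, root seed and produced files, so a rerun with the same config is
byte-identical and fully traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .contigtable import DatasetSummary, build_table, pearson, subset_long, summarize
from .nbmodels import FitResult, SelectionTable, predict_count, run_full_selection
from .snpcall import FilterConfig, call_snps, eligible_contig, write_calls_tsv, write_vcf
from .synthdata import (AlignmentSimConfig, ConfigError,
                        read_flat_config, simulate_alignments,
                        write_count_table_tsv, write_fasta, write_qual,
                        write_sam, write_truth_tsv)

__all__ = ["RunConfig", "run_pipeline", "render_tables",
           "format_weight", "format_mean"]

log = logging.getLogger("snpfreq")

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_STAGE = 3


@dataclass(frozen=True)
class RunConfig:
    """Stage toggles, paths and sub-configs for one pipeline run."""

    outdir: Path = Path("snpfreq_run")
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "call", "table", "fit", "report")
    alignment_sim: AlignmentSimConfig = field(default_factory=AlignmentSimConfig)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    long_dataset: bool = False
    prediction_lengths: tuple[int, ...] = (500, 1000, 2000, 4000)
    prediction_depths: tuple[int, ...] = (10, 50, 100, 200)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        parsed = read_flat_config(path)
        kwargs: dict = {}
        if parsed.get("alignment"):
            kwargs["alignment_sim"] = AlignmentSimConfig(**parsed["alignment"])
        if "seed" in parsed:
            kwargs["seed"] = parsed["seed"]
        kwargs.update(overrides)
        if "seed" in kwargs and "alignment_sim" in kwargs:
            kwargs["alignment_sim"] = dataclasses.replace(
                kwargs["alignment_sim"], seed=kwargs["seed"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name))
                        for f in dataclasses.fields(o)}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, Path):
                return str(o)
            return o
        payload = enc(self)
        payload.pop("outdir", None)  # where outputs land is not part of the run identity
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# report formatting
# ---------------------------------------------------------------------------

def format_weight(w: float) -> str:
    """Akaike-weight display: 3 decimals, or ``m x 10^-e`` below 1e-3."""
    if w != 0 and w < 1e-3:
        exponent = math.floor(math.log10(w))
        mantissa = w / 10 ** exponent
        if round(mantissa, 1) >= 10.0:  # 9.97 rounds up a decade
            mantissa /= 10.0
            exponent += 1
        return f"{mantissa:.1f} × 10^{exponent}"
    return f"{w:.3f}"


def format_mean(x: float) -> str:
    """Report-style mean: rounded to the nearest integer."""
    return f"{round(x):d}"


def render_tables(summary_all: DatasetSummary | None,
                  summary_long: DatasetSummary | None,
                  selections: dict[str, tuple[SelectionTable, FitResult, list[FitResult]]] | None,
                  ) -> str:
    """Plain-text report mirroring the summary / selection / coefficient tables."""
    lines: list[str] = []

    def summary_block(title: str, s: DatasetSummary) -> None:
        lines.append(title)
        lines.append("\tTotal\tProtein-coding\tNon-coding")
        for label, attr in [("Number of contigs", "n_contigs"),
                            ("Mean length (bp)", "mean_length"),
                            ("Mean depth", "mean_depth"),
                            ("Number of SNPs", "total_snp"),
                            ("Number of transitions", "total_ti"),
                            ("Number of transversions", "total_tv")]:
            vals = []
            for part in (s.overall, s.coding, s.noncoding):
                v = getattr(part, attr)
                if isinstance(v, float):
                    vals.append(format_mean(v) if not math.isnan(v) else "0")
                else:
                    vals.append(str(v))
            lines.append(label + "\t" + "\t".join(vals))
        lines.append("")

    if summary_all is not None:
        summary_block("Summary: contigs of 100 bp or longer", summary_all)
    if summary_long is not None:
        summary_block("Summary: contigs of 501 bp or longer", summary_long)

    if selections:
        lines.append("Model selection (AIC / ΔAIC / Akaike weight)")
        for response, (table, best, fits) in selections.items():
            lines.append(f"response: {response}")
            lines.append("model\tcovariates\tAIC\tdAIC\tw")
            for r in table.rows:
                lines.append(f"{r.model}\t{'+'.join(r.covariates)}\t"
                             f"{r.aic:.1f}\t{r.delta_aic:.1f}\t"
                             f"{format_weight(r.weight)}")
            lines.append("")
            lines.append(f"best-model coefficients ({best.spec.name}, {response})")
            lines.append("parameter\testimate\tci_low\tci_high\tP")
            for nm, b in best.beta.items():
                lo, hi = best.ci95[nm] if best.ci95 else (float("nan"),) * 2
                p = best.wald_p[nm] if best.wald_p else float("nan")
                lines.append(f"{nm}\t{b:.4f}\t{lo:.4f}\t{hi:.4f}\t{p:.4g}")
            lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary.

    Writes, under ``config.outdir``: simulated inputs (FASTA/QUAL/SAM, truth
    TSVs), calls (VCF + TSV), the contig table, summary/selection/coefficient
    reports, a prediction grid, and ``manifest.json``.
    """
    cfg = dataclasses.replace(
        config, alignment_sim=dataclasses.replace(config.alignment_sim,
                                                  seed=config.seed))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "version": __version__, "stages": list(cfg.stages),
                "outputs": []}
    produced = manifest["outputs"]

    fcfg = (cfg.filter_config.long_variant() if cfg.long_dataset
            else cfg.filter_config)
    alignments = truth = None
    calls = None
    records = None

    def _stage(name):
        log.info("stage %s", name)

    try:
        if "simulate" in cfg.stages:
            _stage("simulate")
            alignments, truth = simulate_alignments(cfg.alignment_sim, fcfg)
            write_fasta(alignments, outdir / "consensus.fasta")
            write_qual(alignments, outdir / "consensus.qual")
            write_sam(alignments, outdir / "reads.sam")
            write_truth_tsv(truth, outdir / "truth_variants.tsv",
                            outdir / "truth_decoys.tsv",
                            outdir / "labels.tsv")
            produced += ["consensus.fasta", "consensus.qual", "reads.sam",
                         "truth_variants.tsv", "truth_decoys.tsv", "labels.tsv"]

        if "call" in cfg.stages:
            _stage("call")
            if alignments is None:
                raise RuntimeError("call stage needs the simulate stage "
                                   "(external inputs go through the CLI "
                                   "`call` subcommand)")
            calls = [c for a in alignments for c in call_snps(a, fcfg)]
            write_vcf(calls, outdir / "calls.vcf")
            write_calls_tsv(calls, outdir / "calls.tsv")
            produced += ["calls.vcf", "calls.tsv"]

        if "table" in cfg.stages:
            _stage("table")
            if calls is None or alignments is None or truth is None:
                raise RuntimeError("table stage needs simulate and call stages")
            meta = {a.contig_id: (a.length, a.depth) for a in alignments
                    if eligible_contig(a, fcfg)}
            records = build_table(calls, meta, truth.labels)
            write_count_table_tsv(records, outdir / "contig_table.tsv")
            produced.append("contig_table.tsv")

        selections = None
        summary_all = summary_long = None
        if "fit" in cfg.stages:
            _stage("fit")
            if records is None:
                raise RuntimeError("fit stage needs the table stage")
            selections = run_full_selection(records)
            for response, (table, best, _fits) in selections.items():
                table.to_frame().to_csv(
                    outdir / f"selection_{response}.tsv", sep="\t", index=False)
                produced.append(f"selection_{response}.tsv")
            grid_rows = []
            best_snp = selections["snp"][1]
            for L in cfg.prediction_lengths:
                for d in cfg.prediction_depths:
                    for c in (0, 1):
                        kw = {}
                        if "length" in best_snp.spec.covariates:
                            kw["length"] = L
                        if "depth" in best_snp.spec.covariates:
                            kw["depth"] = d
                        pred = predict_count(best_snp, cnc=c, **kw)
                        grid_rows.append(dict(length=L, depth=d, cnc=c,
                                              expected_snps=pred.mean))
            pd.DataFrame(grid_rows).to_csv(outdir / "prediction_grid.tsv",
                                           sep="\t", index=False)
            produced.append("prediction_grid.tsv")

        if "report" in cfg.stages:
            _stage("report")
            if records is None:
                raise RuntimeError("report stage needs the table stage")
            summary_all = summarize(records)
            long_records = subset_long(records)
            summary_long = summarize(long_records) if len(long_records) else None
            report = render_tables(summary_all, summary_long, selections)
            corr_lines = ["x\ty\tr\tp"]
            for x in ("length", "depth"):
                try:
                    r, p = pearson(records, x, "n_snp")
                    corr_lines.append(f"{x}\tn_snp\t{r:.4f}\t{p:.3g}")
                except ValueError as exc:
                    corr_lines.append(f"{x}\tn_snp\tNA\tNA\t# {exc}")
            (outdir / "correlations.tsv").write_text("\n".join(corr_lines) + "\n")
            (outdir / "report.txt").write_text(report)
            produced += ["correlations.tsv", "report.txt"]
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(f"pipeline stage failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


class StageError(RuntimeError):
    """A pipeline stage failed; exit code 3 at the CLI."""
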