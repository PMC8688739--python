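"""End-to-end report: every figure-level table of the analysis on one manifest.

``run_report`` loads a sample manifest, then emits plain delimited-text
tables: per-sample diversity; overlap/JSD matrices per mouse-and-day and
pooled; blood→organ and gut→organ top-clone rank tables; donor trace-back of
recipient top clones (when a pre-transplant donor sample is present);
cross-recipient shared clones within the top-k; and V/J usage matrices with
an allogeneic-vs-syngeneic comparison when both groups are present.

Every number in every table is produced by the corresponding module
operation — the report only arranges results.  Given identical inputs and
configuration the bundle is byte-for-byte reproducible.  Any stage failure
aborts the run, removes the partial outputs of this run, and names the
failing stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_table
from .gene_usage import compare_usage, comparisons_to_frame, usage_matrix
from .overlap import pairwise_matrix
from .repio import KeyMode, RepertoireSet, load_repertoire_set
from .tracking import (
    cross_recipient_shared,
    donor_traceback,
    rank_in_target,
    top_clones,
    undetectable_fraction,
)

__all__ = ["PipelineConfig", "ReportError", "run_report"]

log = logging.getLogger(__name__)

NA = "NA"


class ReportError(RuntimeError):
    """A report stage failed; the message names the stage and sample."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one report run."""

    manifest: str
    outdir: str
    dialect: str = "airr"
    key: str = "aa"
    topn: tuple[int, ...] = (10, 20, 30)
    top_k: int = 500
    rank_sources: tuple[str, ...] = ("blood", "gut")
    rank_top_n: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("topn", "rank_sources"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, written: list[Path], index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=NA)
    written.append(path)


def _stage_rank_tables(
    reps: RepertoireSet, config: PipelineConfig, outdir: Path, written: list[Path]
) -> None:
    for mouse in reps.mice():
        mouse_set = reps.subset(mouse_id=mouse)
        days = sorted({r.meta.day for r in mouse_set})
        for day in days:
            day_set = mouse_set.subset(day=day)
            tissues = [r.meta.tissue for r in day_set.sorted()]
            for source in config.rank_sources:
                source_id = None
                for r in day_set:
                    if r.meta.tissue == source:
                        source_id = r.sample_id
                if source_id is None:
                    continue
                src = day_set[source_id]
                tops = top_clones(src, config.rank_top_n)
                rows = []
                for clone in tops:
                    row = {
                        "source_rank": clone.rank,
                        "cdr3_aa": clone.cdr3_aa,
                        "v_gene": clone.v_gene,
                        "j_gene": clone.j_gene,
                        "source_frequency": clone.frequency,
                    }
                    for tissue in tissues:
                        if tissue == source:
                            continue
                        target = next(r for r in day_set if r.meta.tissue == tissue)
                        (_, rank), = rank_in_target([clone], target)
                        row[f"rank_in_{tissue}"] = rank
                    rows.append(row)
                _write(
                    pd.DataFrame(rows),
                    outdir / f"ranks_{source}_{mouse}_d{day}.tsv",
                    written,
                )


def _stage_traceback(
    reps: RepertoireSet, config: PipelineConfig, outdir: Path, written: list[Path]
) -> None:
    donors = [r for r in reps if r.meta.group == "donor_pretransplant"]
    if not donors:
        log.info("no pre-transplant donor sample in manifest; skipping trace-back")
        return
    donor = donors[0]
    rows = []
    for rep in reps.sorted():
        if rep.meta.group == "donor_pretransplant" or rep.meta.tissue not in config.rank_sources:
            continue
        tops = top_clones(rep, config.rank_top_n)
        traces = donor_traceback(tops, donor, source_sample=rep.sample_id)
        for clone, tr in zip(tops, traces):
            rows.append(
                {
                    "source_sample": rep.sample_id,
                    "group": rep.meta.group,
                    "tissue": rep.meta.tissue,
                    "day": rep.meta.day,
                    "source_rank": clone.rank,
                    "cdr3_aa": clone.cdr3_aa,
                    "source_frequency": clone.frequency,
                    "donor_templates": tr.donor_templates,
                    "donor_frequency": tr.donor_frequency,
                    "detectable_in_donor": tr.detectable_in_donor,
                }
            )
        rows.append(
            {
                "source_sample": rep.sample_id,
                "group": rep.meta.group,
                "tissue": rep.meta.tissue,
                "day": rep.meta.day,
                "source_rank": "undetectable_fraction",
                "cdr3_aa": NA,
                "source_frequency": float("nan"),
                "donor_templates": 0,
                "donor_frequency": undetectable_fraction(traces),
                "detectable_in_donor": False,
            }
        )
    if rows:
        _write(pd.DataFrame(rows), outdir / "traceback.tsv", written)


def _stage_shared(
    reps: RepertoireSet, config: PipelineConfig, outdir: Path, written: list[Path]
) -> None:
    for group in ("syngeneic", "allogeneic"):
        group_set = reps.subset(group=group)
        if len(group_set) == 0:
            continue
        days = sorted({r.meta.day for r in group_set})
        for day in days:
            day_set = group_set.subset(day=day)
            mice = day_set.mice()
            if len(mice) < 2:
                continue
            by_mouse = {m: day_set.subset(mouse_id=m) for m in mice}
            shared = cross_recipient_shared(by_mouse, top_k=config.top_k)
            rows = [
                {"cdr3_aa": s.cdr3_aa, "key": "|".join(map(str, s.key)),
                 **{f"rank_{m}": s.ranks[m] for m in mice}}
                for s in shared
            ]
            _write(
                pd.DataFrame(rows, columns=["cdr3_aa", "key", *(f"rank_{m}" for m in mice)]),
                outdir / f"shared_top{config.top_k}_{group}_d{day}.tsv",
                written,
            )


def _stage_usage(
    reps: RepertoireSet, config: PipelineConfig, outdir: Path, written: list[Path]
) -> None:
    recipients = RepertoireSet(
        [r for r in reps if r.meta.group != "donor_pretransplant"], key=reps.key
    ) if any(r.meta.group != "donor_pretransplant" for r in reps) else reps
    for segment in ("V", "J"):
        mat = usage_matrix(recipients, segment=segment)
        _write(mat, outdir / f"usage_{segment}.tsv", written, index=True)
        allo = recipients.subset(group="allogeneic")
        syn = recipients.subset(group="syngeneic")
        if len(allo) >= 2 and len(syn) >= 2:
            comp = compare_usage(
                usage_matrix(allo, segment=segment),
                usage_matrix(syn, segment=segment),
                method="anova_sidak",
            )
            frame = comparisons_to_frame(comp).rename(
                columns={
                    "mean_a": "mean_allogeneic",
                    "mean_b": "mean_syngeneic",
                    "sd_a": "sd_allogeneic",
                    "sd_b": "sd_syngeneic",
                }
            )
            frame["direction"] = frame["direction"].map(
                {"a>b": "allo>syn", "a<b": "allo<syn", "a=b": "allo=syn"}
            )
            _write(frame, outdir / f"usage_{segment}_comparison.tsv", written)


def run_report(config: PipelineConfig) -> list[Path]:
    """Run the full pipeline; returns the list of written table paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        reps = load_repertoire_set(
            config.manifest, dialect=config.dialect, key=KeyMode(config.key)
        )
        if len(reps) < 1:
            raise ReportError("manifest contains no samples")

        stage = "diversity"
        _write(pd.DataFrame(diversity_table(reps, topn_list=config.topn)),
               outdir / "diversity.tsv", written)

        stage = "overlap_matrices"
        for mouse in reps.mice():
            mouse_set = reps.subset(mouse_id=mouse)
            for day in sorted({r.meta.day for r in mouse_set}):
                day_set = mouse_set.subset(day=day)
                if len(day_set) < 2:
                    continue
                for statistic in ("overlap", "jsd"):
                    mat = pairwise_matrix(day_set, statistic=statistic)
                    _write(mat.values, outdir / f"{statistic}_{mouse}_d{day}.tsv",
                           written, index=True)
        if len(reps) >= 2:
            for statistic in ("overlap", "jsd"):
                mat = pairwise_matrix(reps, statistic=statistic)
                _write(mat.values, outdir / f"{statistic}_all.tsv", written, index=True)

        stage = "rank_tables"
        _stage_rank_tables(reps, config, outdir, written)

        stage = "traceback"
        _stage_traceback(reps, config, outdir, written)

        stage = "shared_clones"
        _stage_shared(reps, config, outdir, written)

        stage = "gene_usage"
        _stage_usage(reps, config, outdir, written)

        stage = "run_log"
        log_path = outdir / "run_log.txt"
        with open(log_path, "w") as fh:
            fh.write(f"clonetrace version: {__version__}\n")
            fh.write(f"seed: {config.seed}\n")
            fh.write("config:\n")
            for k, v in asdict(config).items():
                fh.write(f"  {k}: {v}\n")
            fh.write("tables:\n")
            for p in written:
                fh.write(f"  {p.name}\n")
        written.append(log_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise ReportError(f"report stage {stage!r} failed: {exc}") from exc
    return written
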