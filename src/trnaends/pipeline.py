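"""End-to-end orchestration: trim -> filter -> map -> classify -> profile.

Every stage keeps exact accounting so the run log can prove conservation:
input reads == kept + dropped; kept == mapped + antisense + unmapped;
mapped == sum of category counts. Identical configuration and inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .align import FilterThresholds, MapResult, ScoringScheme, map_read
from .classify import ClassifiedRead, classify_read
from .profiling import (
    SampleProfile,
    TimeCourse,
    aggregate_replicates,
    count_categories,
    pooled_percentages,
    report,
)
from .reads import Read, filter_read, read_sequences, trim_adapter
from .reference import ReferenceWindow, build_window, load_locus, read_fasta_dict

__all__ = ["RunConfig", "SampleResult", "ConfigError", "process_sample", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    reference_fasta: Union[str, Path]
    locus_bed: Union[str, Path]
    sample_sheet: Union[str, Path]
    out_dir: Union[str, Path]
    adapter: Optional[str] = None
    min_read_len: int = 15
    min_overlap: int = 3
    max_error_rate: float = 0.1
    flank: int = 50
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    include_unclassified_in_percent: bool = False
    plots: bool = True


@dataclass
class SampleResult:
    sample_id: str
    n_input: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)
    n_kept: int = 0
    n_mapped: int = 0
    n_antisense: int = 0
    n_unmapped: int = 0
    unmapped_reasons: dict = field(default_factory=dict)
    classified: list = field(default_factory=list)

    def check_conservation(self) -> None:
        if self.n_input != self.n_kept + self.n_dropped:
            raise AssertionError(f"{self.sample_id}: input != kept + dropped")
        if self.n_kept != self.n_mapped + self.n_antisense + self.n_unmapped:
            raise AssertionError(
                f"{self.sample_id}: kept != mapped + antisense + unmapped"
            )
        if self.n_mapped != len(self.classified):
            raise AssertionError(f"{self.sample_id}: mapped != classified")


def process_sample(
    reads: Iterable[Read],
    window: ReferenceWindow,
    sample_id: str,
    adapter: Optional[str] = None,
    min_read_len: int = 15,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    scoring: ScoringScheme = ScoringScheme(),
    thresholds: FilterThresholds = FilterThresholds(),
) -> SampleResult:
    """Run one sample through trimming, filtering, mapping, classification."""
    res = SampleResult(sample_id=sample_id)
    for read in reads:
        res.n_input += 1
        if adapter:
            read = trim_adapter(read, adapter, min_overlap, max_error_rate)
        keep, reason = filter_read(read, min_len=min_read_len)
        if not keep:
            res.n_dropped += 1
            res.drop_reasons[reason] = res.drop_reasons.get(reason, 0) + 1
            continue
        res.n_kept += 1
        mr: MapResult = map_read(read, window, scoring, thresholds)
        if mr.status == "unmapped":
            res.n_unmapped += 1
            res.unmapped_reasons[mr.reason] = res.unmapped_reasons.get(mr.reason, 0) + 1
        elif mr.status == "antisense":
            res.n_antisense += 1
        else:
            res.n_mapped += 1
            res.classified.append(classify_read(mr.mapped, window))
    res.check_conservation()
    return res


def _load_sample_sheet(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "time_min", "replicate", "fastq"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ConfigError("duplicate sample_id in sample sheet")
    return df


def _write_per_read_tsv(results: list[SampleResult], path: Path) -> None:
    cols = [
        "read_id",
        "sample",
        "gene_start",
        "gene_end",
        "tail",
        "genomic_len5",
        "genomic_len3",
        "category",
        "flags",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols, delimiter="\t")
        w.writeheader()
        for res in results:
            for c in res.classified:
                row = c.to_row()
                row["sample"] = res.sample_id
                w.writerow(row)


def _write_run_log(results: list[SampleResult], path: Path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "input": r.n_input,
                "dropped": r.n_dropped,
                "drop_reasons": ";".join(
                    f"{k}={v}" for k, v in sorted(r.drop_reasons.items())
                ),
                "kept": r.n_kept,
                "mapped": r.n_mapped,
                "antisense": r.n_antisense,
                "unmapped": r.n_unmapped,
                "unmapped_reasons": ";".join(
                    f"{k}={v}" for k, v in sorted(r.unmapped_reasons.items())
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Full run over a sample sheet; returns profiles, time course, artifacts."""
    for p in (config.reference_fasta, config.locus_bed, config.sample_sheet):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    locus = load_locus(config.reference_fasta, config.locus_bed)
    genome = read_fasta_dict(config.reference_fasta)[locus.chrom_id]
    window = build_window(genome, locus, flank=config.flank)

    sheet = _load_sample_sheet(config.sample_sheet)
    base = Path(config.sample_sheet).parent
    results: list[SampleResult] = []
    sample_info: dict[str, dict] = {}
    for _, row in sheet.iterrows():
        fq = Path(row["fastq"])
        if not fq.is_absolute():
            fq = base / fq
        if not fq.exists():
            raise ConfigError(f"FASTQ not found for sample {row['sample_id']}: {fq}")
        sample_info[row["sample_id"]] = {
            "condition": row["condition"],
            "time_min": int(row["time_min"]),
            "replicate": int(row["replicate"]),
        }
        results.append(
            process_sample(
                read_sequences(fq),
                window,
                sample_id=row["sample_id"],
                adapter=config.adapter,
                min_read_len=config.min_read_len,
                min_overlap=config.min_overlap,
                max_error_rate=config.max_error_rate,
                scoring=config.scoring,
                thresholds=config.thresholds,
            )
        )

    labels = [
        (res.sample_id, c.category) for res in results for c in res.classified
    ]
    profiles = count_categories(labels, sample_info=sample_info)
    profile_list = list(profiles.values())
    tc = aggregate_replicates(profile_list)

    per_read = out_dir / "per_read_classification.tsv"
    _write_per_read_tsv(results, per_read)
    run_log = out_dir / "run_log.tsv"
    _write_run_log(results, run_log)
    artifacts = report(tc, out_dir, plots=config.plots)
    artifacts.update({"per_read": per_read, "run_log": run_log})

    # per-sample and pooled-T0 percentage tables
    pct_rows = []
    for p in profile_list:
        if p.classified_total == 0:
            continue
        from .profiling import percentages

        for cat, pc in percentages(
            p, include_unclassified=config.include_unclassified_in_percent
        ).items():
            pct_rows.append(
                {
                    "sample_id": p.sample_id,
                    "condition": p.condition,
                    "time_min": p.time_min,
                    "category": cat,
                    "percent": pc,
                }
            )
    t0 = [p for p in profile_list if p.time_min == 0 and p.classified_total > 0]
    if t0:
        for cat, pc in pooled_percentages(t0).items():
            pct_rows.append(
                {
                    "sample_id": "pooled_T0",
                    "condition": "dormant",
                    "time_min": 0,
                    "category": cat,
                    "percent": pc,
                }
            )
    pct_path = out_dir / "percentages.tsv"
    pd.DataFrame(pct_rows).to_csv(
        pct_path, sep="\t", index=False, float_format="%.6g"
    )
    artifacts["percentages"] = pct_path

    return {
        "window": window,
        "results": results,
        "profiles": profiles,
        "timecourse": tc,
        "artifacts": artifacts,
    }
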