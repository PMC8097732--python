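"""The published study layout: 14 GEO sequencing runs and their read counts.

The packaged table records, for each SRA run of GSE81238, the experimental
condition (dormant spores at T0; outgrowth at 30/60/90 min with or without
1.2 M NaCl), the replicate, the library size and the number of reads that
mapped to the tRNA-Cys locus. It drives the default synthetic study layout
and the desk-scale read-accounting checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_study_runs", "total_mapped_reads", "mean_mapped_at_t0"]


def load_study_runs() -> pd.DataFrame:
    """Run table: run_id, condition, time_min, replicate, total_reads, mapped_reads."""
    with resources.files("trnaends.data").joinpath("study_runs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    expected = {"run_id", "condition", "time_min", "replicate", "total_reads", "mapped_reads"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"study run table missing columns: {sorted(missing)}")
    return df


def total_mapped_reads(runs: pd.DataFrame | None = None) -> int:
    """Sum of locus-mapped reads over all runs."""
    runs = load_study_runs() if runs is None else runs
    return int(runs["mapped_reads"].sum())


def mean_mapped_at_t0(runs: pd.DataFrame | None = None) -> float:
    """Mean locus-mapped reads across the dormant-spore (T0) replicates."""
    runs = load_study_runs() if runs is None else runs
    t0 = runs.loc[runs["time_min"] == 0, "mapped_reads"]
    if t0.empty:
        raise ValueError("no T0 runs in table")
    return float(t0.mean())
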