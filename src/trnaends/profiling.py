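"""Per-sample category profiles, percentages, and replicate aggregation.

Counts are exact integers; percentages are computed over the classified
(I-IX) total by default, with UNCLASSIFIED reported separately, and pooling
sums counts across replicates before dividing. Replicate aggregation
reports the arithmetic mean and the standard error of the mean (sample
standard deviation, n-1 denominator, divided by sqrt(n)); with a single
replicate the SEM is reported as missing, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import CLASSIFIED_CATEGORIES, Category

__all__ = [
    "CONDITIONS",
    "TIMES_MIN",
    "SampleProfile",
    "TimeCourse",
    "count_categories",
    "percentages",
    "pooled_percentages",
    "aggregate_replicates",
    "report",
]

CONDITIONS = ("dormant", "no_nacl", "nacl")
TIMES_MIN = (0, 30, 60, 90)

ALL_CATEGORY_VALUES = [c.value for c in Category]


class ConfigError(ValueError):
    """Sample metadata inconsistent with the observed labels."""


def _as_value(category: Union[Category, str]) -> str:
    return category.value if isinstance(category, Category) else str(category)


@dataclass
class SampleProfile:
    sample_id: str
    condition: str = "dormant"
    time_min: int = 0
    replicate: int = 1
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        clean = {}
        for k, v in self.counts.items():
            k = _as_value(k)
            if k not in ALL_CATEGORY_VALUES:
                raise ConfigError(f"unknown category {k!r}")
            if v < 0:
                raise ConfigError("negative count")
            clean[k] = int(v)
        self.counts = clean

    @property
    def total_mapped(self) -> int:
        return sum(self.counts.values())

    @property
    def classified_total(self) -> int:
        return sum(
            v for k, v in self.counts.items() if k != Category.UNCLASSIFIED.value
        )

    def count(self, category: Union[Category, str]) -> int:
        return self.counts.get(_as_value(category), 0)


def count_categories(
    labels: Iterable[tuple[str, Union[Category, str]]],
    sample_info: Optional[Mapping[str, dict]] = None,
) -> dict[str, SampleProfile]:
    """Tally (sample_id, label) pairs into one profile per sample.

    ``sample_info`` maps sample_id -> {condition, time_min, replicate}; when
    given, a label for an unknown sample is a configuration error, and
    samples listed but never observed yield all-zero profiles.
    """
    tallies: dict[str, dict[str, int]] = {}
    if sample_info is not None:
        for sid in sample_info:
            tallies[sid] = {}
    for sid, label in labels:
        if sample_info is not None and sid not in sample_info:
            raise ConfigError(f"label for unknown sample {sid!r}")
        t = tallies.setdefault(sid, {})
        v = _as_value(label)
        t[v] = t.get(v, 0) + 1
    out = {}
    for sid, counts in tallies.items():
        info = dict(sample_info[sid]) if sample_info is not None else {}
        out[sid] = SampleProfile(
            sample_id=sid,
            condition=info.get("condition", "dormant"),
            time_min=int(info.get("time_min", 0)),
            replicate=int(info.get("replicate", 1)),
            counts=counts,
        )
    return out


def percentages(
    profile: SampleProfile, include_unclassified: bool = False
) -> dict[str, float]:
    """Category -> percent of the classified total (or of all mapped reads)."""
    denom = profile.total_mapped if include_unclassified else profile.classified_total
    if denom == 0:
        raise ZeroDivisionError(
            f"sample {profile.sample_id}: no reads to take percentages of"
        )
    cats = (
        ALL_CATEGORY_VALUES
        if include_unclassified
        else [c.value for c in CLASSIFIED_CATEGORIES]
    )
    return {c: 100.0 * profile.count(c) / denom for c in cats}


def pooled_percentages(
    profiles: Sequence[SampleProfile], include_unclassified: bool = False
) -> dict[str, float]:
    """Percentages from counts summed across replicates, then divided."""
    pooled: dict[str, int] = {}
    for p in profiles:
        for k, v in p.counts.items():
            pooled[k] = pooled.get(k, 0) + v
    merged = SampleProfile(sample_id="pooled", counts=pooled)
    return percentages(merged, include_unclassified=include_unclassified)


@dataclass
class TimeCourse:
    """Replicate means +/- SEM per (condition, time, category).

    ``table`` is indexed by (condition, time_min, category) with columns
    mean, sem, n; sem is NaN when only one replicate exists.
    """

    table: pd.DataFrame

    def mean(self, condition: str, time_min: int, category: Union[Category, str]) -> float:
        return float(self.table.loc[(condition, time_min, _as_value(category)), "mean"])

    def sem(self, condition: str, time_min: int, category: Union[Category, str]) -> float:
        return float(self.table.loc[(condition, time_min, _as_value(category)), "sem"])


def aggregate_replicates(profiles: Sequence[SampleProfile]) -> TimeCourse:
    """Group profiles by (condition, time) and average category counts."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    rows = []
    for p in profiles:
        row = {"condition": p.condition, "time_min": p.time_min, "sample": p.sample_id}
        for c in ALL_CATEGORY_VALUES:
            row[c] = p.count(c)
        row["total"] = p.total_mapped
        rows.append(row)
    df = pd.DataFrame(rows)
    records = []
    for (cond, t), grp in df.groupby(["condition", "time_min"], sort=True):
        n = len(grp)
        for c in ALL_CATEGORY_VALUES + ["total"]:
            vals = grp[c].to_numpy(dtype=float)
            sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            records.append(
                {
                    "condition": cond,
                    "time_min": t,
                    "category": c,
                    "mean": float(vals.mean()),
                    "sem": sem,
                    "n": n,
                }
            )
    table = pd.DataFrame(records).set_index(["condition", "time_min", "category"])
    return TimeCourse(table=table)


def report(
    tc: TimeCourse,
    out_dir: Union[str, Path],
    plots: bool = True,
) -> dict[str, Path]:
    """Write the wide time-course TSV and per-category trend plots.

    The TSV has one row per category and one (mean, sem) column pair per
    condition x time; identical input produces byte-identical output.
    """
    if tc.table.empty:
        raise ValueError("empty time course")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wide = tc.table.reset_index().pivot(
        index="category", columns=["condition", "time_min"], values=["mean", "sem"]
    )
    wide = wide.reorder_levels([1, 2, 0], axis=1).sort_index(axis=1)
    wide.columns = [f"{c}_T{t}_{stat}" for c, t, stat in wide.columns]
    order = [c for c in ALL_CATEGORY_VALUES + ["total"] if c in wide.index]
    wide = wide.loc[order]
    tsv_path = out_dir / "timecourse.tsv"
    wide.to_csv(tsv_path, sep="\t", float_format="%.6g")
    artifacts = {"timecourse": tsv_path}

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plain = tc.table.reset_index()
        for c in ALL_CATEGORY_VALUES:
            sub = plain[plain["category"] == c]
            if sub.empty or (sub["mean"] == 0).all():
                continue
            fig, ax = plt.subplots(figsize=(4, 3))
            for cond, grp in sub.groupby("condition"):
                grp = grp.sort_values("time_min")
                ax.errorbar(
                    grp["time_min"],
                    grp["mean"],
                    yerr=grp["sem"].fillna(0.0),
                    marker="o",
                    capsize=3,
                    label=cond,
                )
            ax.set_xlabel("time after germination (min)")
            ax.set_ylabel("mean mapped reads")
            ax.set_title(f"category {c}")
            ax.legend(fontsize=8)
            fig.tight_layout()
            p = out_dir / f"trend_category_{c}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            artifacts[f"plot_{c}"] = p
    return artifacts
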