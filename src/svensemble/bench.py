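"""Benchmarking of call sets against SV truth sets.

A test call is a true positive when a same-type truth call on the same
contig lies within ±``window`` bp (inclusive, default 500) of its start
position.  Matching is one-to-one greedy nearest-distance: candidate
(truth, test) pairs are sorted by distance and accepted only while both
endpoints are unmatched — the only reading under which
``FP = |TEST| − TP`` and ``FN = |TRUTH| − TP`` are consistent.  Deletions
and insertions are always evaluated separately.

Per-evaluation metrics::

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the 0/0 convention → 0.  Metrics combined across datasets are
micro-averages over the summed TP/FP/FN.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .records import SVRecord

__all__ = [
    "ConfusionCounts",
    "MetricsRow",
    "CombinedMetrics",
    "match_to_truth",
    "restrict_to_regions",
    "compute_metrics",
    "combine_micro",
    "evaluation_report",
    "round2",
    "load_benchmark_counts",
    "audit_counts",
    "counts_to_confusions",
]


def round2(x: float) -> float:
    """Round to 2 decimals with the half-up convention (0.625 → 0.63)."""
    return float(Decimal(repr(float(x))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN for one (dataset, SV type, call set) evaluation."""

    dataset: str
    svtype: str
    test_total: int
    tp: int
    fp: int
    fn: int
    callset: str = ""

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.test_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp != self.test_total:
            raise ValueError("tp + fp must equal test_total")

    @property
    def truth_total(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricsRow:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class CombinedMetrics:
    cpr: float
    crc: float
    cf1: float


def match_to_truth(
    test: Sequence[SVRecord],
    truth: Sequence[SVRecord],
    svtype: Optional[str] = None,
    window: int = 500,
    dataset: str = "",
    callset: str = "",
    return_pairs: bool = False,
):
    """Match a test call set against a truth set of one SV type.

    Candidate pairs are same-contig, same-type pairs with an inclusive
    start-distance of at most ``window``; assignment is one-to-one greedy by
    ascending distance (ties by truth then test position).  Returns a
    :class:`ConfusionCounts`, plus the accepted (truth, test) pairs when
    ``return_pairs`` is set.
    """
    if svtype is not None:
        for name, recs in (("test", test), ("truth", truth)):
            bad = [r for r in recs if r.svtype != svtype]
            if bad:
                raise ValueError(
                    f"{name} set contains {bad[0].svtype} records but "
                    f"svtype={svtype} was requested"
                )
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for j, t in enumerate(truth):
        by_contig.setdefault(t.contig, []).append((t.pos, j))
    candidates = []
    for i, r in enumerate(test):
        for t_pos, j in by_contig.get(r.contig, ()):
            d = abs(t_pos - r.pos)
            if d <= window:
                candidates.append((d, t_pos, r.pos, j, i))
    candidates.sort()
    matched_truth: set[int] = set()
    matched_test: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for d, _tp, _rp, j, i in candidates:
        if j in matched_truth or i in matched_test:
            continue
        matched_truth.add(j)
        matched_test.add(i)
        pairs.append((j, i))
    tp = len(pairs)
    counts = ConfusionCounts(
        dataset=dataset,
        svtype=svtype or (test[0].svtype if test else
                          truth[0].svtype if truth else ""),
        test_total=len(test),
        tp=tp,
        fp=len(test) - tp,
        fn=len(truth) - tp,
        callset=callset,
    )
    if return_pairs:
        return counts, [(truth[j], test[i]) for j, i in pairs]
    return counts


def _load_bed(source: Union[str, Iterable]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}

    def add(contig, start, end):
        if end <= start:
            return
        trees.setdefault(contig, IntervalTree()).addi(start, end)

    if isinstance(source, str):
        with open(source) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                try:
                    add(fields[0], int(fields[1]), int(fields[2]))
                except (IndexError, ValueError) as exc:
                    raise ValueError(
                        f"malformed BED line {lineno}: {line!r}"
                    ) from exc
    else:
        for contig, start, end in source:
            add(contig, int(start), int(end))
    return trees


def restrict_to_regions(
    records: Sequence[SVRecord], regions: Union[str, Iterable]
) -> list[SVRecord]:
    """Keep records whose start falls inside a confident region.

    ``regions`` is a BED path or an iterable of (contig, start, end) with
    0-based half-open coordinates; a record is kept when its POS lies inside
    a region on that half-open axis, so a record at the region's end
    coordinate is excluded.
    """
    trees = _load_bed(regions)
    return [
        r for r in records
        if r.contig in trees and trees[r.contig].overlaps_point(r.pos)
    ]


def compute_metrics(c: ConfusionCounts) -> MetricsRow:
    """Precision, recall, and F1 from one confusion-count triple."""
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return MetricsRow(precision=precision, recall=recall, f1=f1)


def combine_micro(counts: Sequence[ConfusionCounts]) -> CombinedMetrics:
    """Micro-averaged metrics over summed TP/FP/FN across datasets."""
    if not counts:
        raise ValueError("combine_micro requires at least one count set")
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    cpr = tp / (tp + fp) if tp + fp else 0.0
    crc = tp / (tp + fn) if tp + fn else 0.0
    cf1 = 2 * cpr * crc / (cpr + crc) if cpr + crc else 0.0
    return CombinedMetrics(cpr=cpr, crc=crc, cf1=cf1)


def _metric_columns(tp, fp, fn):
    c = ConfusionCounts("", "DEL", tp + fp, tp, fp, fn)
    m = compute_metrics(c)
    return {
        "recall": round2(m.recall),
        "precision": round2(m.precision),
        "f1": round2(m.f1),
        "recall_full": m.recall,
        "precision_full": m.precision,
        "f1_full": m.f1,
    }


def evaluation_report(
    counts: Sequence[ConfusionCounts],
) -> dict[str, pd.DataFrame]:
    """Build per-dataset metric tables plus a combined micro-average table.

    Row order within a table follows the input order of (callset, svtype)
    first appearances.  Metrics appear both half-up-rounded to two decimals
    (the reporting convention) and at full precision.
    """
    frames: dict[str, pd.DataFrame] = {}
    datasets: list[str] = []
    for c in counts:
        if c.dataset not in datasets:
            datasets.append(c.dataset)
    callset_order: list[tuple[str, str]] = []
    for c in counts:
        key = (c.callset, c.svtype)
        if key not in callset_order:
            callset_order.append(key)

    for ds in datasets:
        rows = []
        for callset, svtype in callset_order:
            sub = [
                c for c in counts
                if c.dataset == ds and c.callset == callset
                and c.svtype == svtype
            ]
            for c in sub:
                rows.append({
                    "callset": c.callset, "svtype": c.svtype,
                    "total": c.test_total, "tp": c.tp, "fp": c.fp,
                    "fn": c.fn, **_metric_columns(c.tp, c.fp, c.fn),
                })
        frames[ds] = pd.DataFrame(rows)

    combined_rows = []
    for callset, svtype in callset_order:
        sub = [
            c for c in counts
            if c.callset == callset and c.svtype == svtype
        ]
        if not sub:
            continue
        tp = sum(c.tp for c in sub)
        fp = sum(c.fp for c in sub)
        fn = sum(c.fn for c in sub)
        combined_rows.append({
            "callset": callset, "svtype": svtype,
            "total": tp + fp, "tp": tp, "fp": fp, "fn": fn,
            **_metric_columns(tp, fp, fn),
        })
    frames["combined"] = pd.DataFrame(combined_rows)
    return frames


# ---------------------------------------------------------------------------
# Counts-only mode: reference benchmark counts for six short-read callers on
# HG002 (GIAB v0.6 Tier 1) and HG00514/HG00733/NA19240 (HGSVC2) serve as an
# exact regression fixture for the metric formulas — no genomic data needed.

def load_benchmark_counts() -> pd.DataFrame:
    """Reference per-dataset and combined TP/FP/FN counts with the metric
    values as originally reported (2-decimal)."""
    ref = importlib.resources.files("svensemble.data") / "benchmark_counts.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def audit_counts(df: pd.DataFrame) -> list[str]:
    """Internal-consistency audit of a counts table.

    Checks, per row, ``total == tp + fp``; per dataset × svtype, a constant
    truth total ``tp + fn``; and, when a ``combined`` dataset is present,
    that its counts equal the sums of the per-dataset rows.  Returns a list
    of human-readable violations (empty when the table is consistent).
    """
    problems: list[str] = []
    for _, row in df.iterrows():
        if row["total"] != row["tp"] + row["fp"]:
            problems.append(
                f"{row['dataset']} {row['callset']} {row['svtype']}: "
                f"total {row['total']} != tp+fp {row['tp'] + row['fp']}"
            )
    per = df[df["dataset"] != "combined"]
    truth = per.assign(truth=per["tp"] + per["fn"])
    for (ds, svtype), grp in truth.groupby(["dataset", "svtype"]):
        if grp["truth"].nunique() > 1:
            problems.append(
                f"{ds} {svtype}: inconsistent truth totals "
                f"{sorted(grp['truth'].unique())}"
            )
    comb = df[df["dataset"] == "combined"]
    if len(comb) and len(per):
        sums = per.groupby(["callset", "svtype"])[
            ["total", "tp", "fp", "fn"]
        ].sum()
        for _, row in comb.iterrows():
            key = (row["callset"], row["svtype"])
            if key not in sums.index:
                continue
            for col in ("total", "tp", "fp", "fn"):
                expect = sums.loc[key, col]
                if row[col] != expect:
                    problems.append(
                        f"combined {row['callset']} {row['svtype']}: "
                        f"{col} {row[col]} != per-dataset sum {expect}"
                    )
    return problems


def counts_to_confusions(df: pd.DataFrame) -> list[ConfusionCounts]:
    """Turn a (dataset, callset, svtype, tp, fp, fn) table into counts."""
    out = []
    for _, row in df.iterrows():
        out.append(ConfusionCounts(
            dataset=str(row["dataset"]),
            svtype=str(row["svtype"]),
            test_total=int(row["tp"]) + int(row["fp"]),
            tp=int(row["tp"]),
            fp=int(row["fp"]),
            fn=int(row["fn"]),
            callset=str(row["callset"]),
        ))
    return out
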