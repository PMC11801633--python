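"""Neighbor grouping and multi-caller combination strategies.

Calls pooled across a caller panel are grouped per (contig, SV type) with an
anchored left-to-right sweep: after sorting by position (ties broken by
caller label then record ID), the first call opens a group and becomes its
representative; each subsequent call joins the open group iff its start lies
within ``window`` bp of the representative's start, and otherwise opens a new
group.  Anchoring (rather than transitive single-linkage chaining) guarantees
every member sits within the window of its representative — the stated
grouping contract — which chaining would violate.

Strategies over the groups:

- ``multiple_agreement`` — emit representatives of groups supported by at
  least ``min_support`` distinct callers (higher precision).
- ``union`` — emit every group's representative (higher recall).
- ``direct_merge`` — concatenate the pooled refined calls without grouping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .records import SVRecord, StrategyConfig, contig_sort_key

__all__ = [
    "NeighborGroup",
    "group_neighbors",
    "apply_strategy",
    "concordance_counts",
    "group_distance_summary",
    "group_size_counts",
]


@dataclass(frozen=True)
class NeighborGroup:
    """Calls on one contig of one SV type within ``window`` bp of the
    smallest-position member (the representative)."""

    contig: str
    svtype: str
    members: tuple[SVRecord, ...]

    @property
    def representative(self) -> SVRecord:
        return self.members[0]

    @property
    def supporting_callers(self) -> frozenset:
        return frozenset(m.caller for m in self.members)


def _sort_key(rec: SVRecord):
    return (rec.pos, rec.caller or "", rec.record_id or "")


def group_neighbors(
    records: Sequence[SVRecord], cfg: StrategyConfig
) -> list[NeighborGroup]:
    """Partition pooled caller-tagged calls into neighbor groups.

    Every input record lands in exactly one group; records from one caller
    may share a group.  Output order is deterministic: natural contig order,
    then SV type, then representative position.
    """
    for rec in records:
        if not rec.caller:
            raise ValueError(
                f"untagged record {rec.contig}:{rec.pos} — run tag_caller first"
            )
    ckey = contig_sort_key()
    buckets: dict[tuple, list[SVRecord]] = {}
    for rec in records:
        buckets.setdefault((rec.contig, rec.svtype), []).append(rec)

    groups: list[NeighborGroup] = []
    for (contig, svtype) in sorted(
        buckets, key=lambda k: (ckey(k[0]), k[1])
    ):
        members: list[SVRecord] = []
        anchor: Optional[int] = None
        for rec in sorted(buckets[(contig, svtype)], key=_sort_key):
            if anchor is not None and rec.pos - anchor <= cfg.window:
                members.append(rec)
            else:
                if members:
                    groups.append(NeighborGroup(contig, svtype, tuple(members)))
                members = [rec]
                anchor = rec.pos
        if members:
            groups.append(NeighborGroup(contig, svtype, tuple(members)))
    return groups


def _merged_representative(group: NeighborGroup, cfg: StrategyConfig) -> SVRecord:
    rep = group.representative
    panel_rank = {name: i for i, name in enumerate(cfg.panel)}
    callers = sorted(
        group.supporting_callers,
        key=lambda c: (panel_rank.get(c, len(panel_rank)), c),
    )
    extra = dict(rep.extra_info)
    extra["SUPP"] = len(group.supporting_callers)
    extra["GROUP_SIZE"] = len(group.members)
    return replace(rep, caller=",".join(callers), extra_info=extra)


def apply_strategy(
    groups: Sequence[NeighborGroup],
    cfg: StrategyConfig,
    pooled: Optional[Sequence[SVRecord]] = None,
) -> list[SVRecord]:
    """Emit the merged call set for one strategy.

    ``direct_merge`` ignores the groups and requires the pooled refined
    records.  Output is sorted by (natural contig order, position).
    """
    ckey = contig_sort_key()
    if cfg.strategy == "direct_merge":
        if pooled is None:
            raise ValueError("direct_merge requires the pooled records")
        return sorted(pooled, key=lambda r: (ckey(r.contig), r.pos,
                                             r.caller or "", r.record_id or ""))
    if cfg.strategy == "multiple_agreement":
        chosen = [
            g for g in groups if len(g.supporting_callers) >= cfg.min_support
        ]
    elif cfg.strategy == "union":
        chosen = list(groups)
    else:
        raise ValueError(f"unknown strategy {cfg.strategy!r}")
    merged = [_merged_representative(g, cfg) for g in chosen]
    return sorted(merged, key=lambda r: (ckey(r.contig), r.pos))


def concordance_counts(
    groups: Sequence[NeighborGroup], cfg: StrategyConfig
) -> dict[frozenset, int]:
    """Tabulate groups by their exact supporting-caller subset.

    The counts over all non-empty subsets sum to the number of groups; the
    table is the input for a Venn-style concordance plot.
    """
    counts: Counter = Counter(g.supporting_callers for g in groups)
    return dict(counts)


def group_size_counts(groups: Sequence[NeighborGroup]) -> dict[int, int]:
    """Distribution of member counts across groups."""
    return dict(Counter(len(g.members) for g in groups))


def group_distance_summary(
    groups: Sequence[NeighborGroup],
) -> Optional[dict[str, float]]:
    """Summary of member-to-representative start distances.

    Distances are collected over all non-representative members; quartiles
    are linearly interpolated.  Returns ``None`` when every group is a
    singleton.
    """
    distances = [
        m.pos - g.representative.pos for g in groups for m in g.members[1:]
    ]
    if not distances:
        return None
    arr = np.asarray(distances, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "count": float(arr.size),
        "median": float(med),
        "iqr": float(q3 - q1),
        "max": float(arr.max()),
    }
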