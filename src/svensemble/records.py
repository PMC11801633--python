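"""Core domain types for multi-caller structural-variant (SV) analysis.

An :class:`SVRecord` is one refined SV call: a contig, a 1-based start
position, an SV type (DEL, INS, DUP, INV, or CTX for inter-chromosomal
translocations), an optional length, the VCF FILTER labels, and the label of
the caller that produced it.  All downstream stages — neighbor grouping,
combination strategies, and benchmarking against a truth set — operate on
sequences of these records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

SV_TYPES = ("DEL", "INS", "DUP", "INV", "CTX")

#: Preset caller panels: the three-caller (III) and five-caller (V) ensembles.
PANELS: Mapping[str, tuple[str, ...]] = {
    "III": ("Manta", "DELLY", "GRIDSS"),
    "V": ("Manta", "DELLY", "GRIDSS", "LUMPY", "SvABA"),
}

STRATEGIES = ("multiple_agreement", "union", "direct_merge")


def natural_key(name: str) -> tuple:
    """Sort key that orders embedded integers numerically (chr2 < chr10)."""
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in re.split(r"(\d+)", name)
        if tok != ""
    )


def contig_sort_key(contig_order: Optional[Mapping[str, int]] = None):
    """Return a contig sort key honouring an explicit order with natural-sort
    fallback for contigs missing from it."""

    def key(contig: str):
        if contig_order is not None and contig in contig_order:
            return (0, contig_order[contig], ())
        return (1, 0, natural_key(contig))

    return key


@dataclass(frozen=True)
class SVRecord:
    """One refined structural-variant call.

    Attributes
    ----------
    contig : str
        Chromosome name.
    pos : int
        1-based start coordinate (VCF POS).
    svtype : str
        One of ``DEL``, ``INS``, ``DUP``, ``INV``, ``CTX``.
    end : int, optional
        1-based inclusive end coordinate, absent for insertions and
        translocations without a resolved partner.
    svlen : int, optional
        Non-negative length in bp; absent for CTX and for symbolic
        insertions whose length the caller did not report.
    filter : frozenset of str
        FILTER labels; ``{"PASS"}`` for a passing call.
    caller : str, optional
        Label of the caller that produced the call (set by tagging).
    record_id, mate_id, mate_contig : str, optional
        Original VCF ID and, for breakend records, the partner's ID and
        contig.
    extra_info : mapping
        Opaque passthrough of remaining INFO keys.
    """

    contig: str
    pos: int
    svtype: str
    end: Optional[int] = None
    svlen: Optional[int] = None
    filter: frozenset = frozenset({"PASS"})
    caller: Optional[str] = None
    record_id: Optional[str] = None
    mate_id: Optional[str] = None
    mate_contig: Optional[str] = None
    extra_info: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svlen is not None and self.svlen < 0:
            raise ValueError("svlen must be non-negative")
        if (
            self.end is not None
            and self.mate_contig is None
            and self.end < self.pos
        ):
            raise ValueError(f"end {self.end} < pos {self.pos}")

    def with_caller(self, caller: str) -> "SVRecord":
        return replace(self, caller=caller)


@dataclass(frozen=True)
class RefineConfig:
    """Thresholds for the four-step call-set refinement.

    ``min_size`` is the minimum SV length kept (calls *smaller* than this are
    excluded, so the boundary value itself survives); ``pass_only`` keeps only
    calls whose FILTER is exactly PASS; ``dedup_paired`` collapses paired
    start/end records of the same SV to the start record.
    """

    min_size: int = 50
    pass_only: bool = True
    dedup_paired: bool = True

    def __post_init__(self):
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")


@dataclass(frozen=True)
class StrategyConfig:
    """Configuration of a multi-caller combination strategy.

    ``window`` is the breakpoint-distance threshold in bp: pooled calls on one
    contig with one SV type whose start positions lie within ``window`` of the
    group's smallest-position member form a neighbor group.  Under
    ``multiple_agreement`` only groups supported by at least ``min_support``
    distinct callers are emitted; ``union`` emits every group's
    representative; ``direct_merge`` concatenates the pooled calls unmerged.
    """

    panel: tuple[str, ...]
    strategy: str = "union"
    window: int = 500
    min_support: int = 2

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.strategy == "multiple_agreement" and self.min_support < 2:
            raise ValueError("min_support must be >= 2 for multiple_agreement")
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("panel labels must be unique")
        object.__setattr__(self, "panel", tuple(self.panel))
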