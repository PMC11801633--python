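"""Four-step refinement of raw caller call sets.

The refinement pipeline applied to every caller VCF, in order:

1. **Annotation** — resolve the SV type and length of each raw row from, in
   priority order, the INFO ``SVTYPE`` key, a symbolic ALT token, or the
   REF/ALT length difference of a sequence-resolved allele.  Breakend (BND)
   records with a same-contig mate are classified DEL/DUP/INV from the
   junction orientation; inter-contig breakends are translocations (CTX).
2. **Size exclusion** — calls shorter than ``min_size`` (50 bp by default)
   are removed.  CTX calls (no length) and symbolic insertions of unknown
   length are kept.
3. **Record deduplication** — callers that emit separate start and end
   records for one SV (linked by MATEID, a shared EVENT, or a shared ID stem
   with ``_1``/``_2`` suffixes) are collapsed to the start record: the
   partner with the larger position (or later contig) is dropped.
4. **Final filtering** — only calls whose FILTER is exactly ``PASS`` are
   retained.

Records are additionally tagged with the caller label, which downstream
grouping requires.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import RefineConfig, SVRecord, contig_sort_key
from .vcfio import RawVariant, parse_breakend_alt, read_caller_vcf, vcf_contig_order

__all__ = [
    "read_caller_vcf",
    "annotate_sv",
    "annotate_all",
    "filter_min_size",
    "deduplicate_paired",
    "filter_pass",
    "tag_caller",
    "summarize_lengths",
    "refine_records",
    "refine_vcf",
    "RefineStats",
]

logger = logging.getLogger(__name__)

_SYMBOLIC_RE = re.compile(r"^<([^<>]+)>$")
_STEM_RE = re.compile(r"^(.*)_([12])$")

_KNOWN_TYPES = {"DEL", "INS", "DUP", "INV", "CTX"}


@dataclass
class RefineStats:
    """Per-step record counters for one refined call set."""

    caller: str = ""
    input_rows: int = 0
    dropped_unclassifiable: int = 0
    removed_size: int = 0
    removed_dedup: int = 0
    dedup_warnings: int = 0
    removed_filter: int = 0
    output: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _info_svtype(info: Mapping) -> Optional[str]:
    raw = info.get("SVTYPE")
    if raw is None:
        return None
    token = str(raw).upper().split(":")[0]
    if token in _KNOWN_TYPES:
        return token
    if token == "TRA":
        return "CTX"
    if token == "BND":
        return "BND"
    return None


def _classify_breakend(contig: str, pos: int, alt: str):
    """Classify a breakend by junction orientation.

    For a same-contig mate the junction layout determines the type:
    sequence-then-``[`` pointing at a larger coordinate (or ``]``-then-
    sequence pointing at a smaller one) is a deletion junction; the converse
    is a tandem duplication; matching-side orientations are an inversion.
    """
    parsed = parse_breakend_alt(alt)
    if parsed is None:
        return None
    mate_contig, mate_pos, form = parsed
    if mate_contig != contig:
        return "CTX", mate_contig, mate_pos, None
    if form in ("t]", "[t"):
        svtype = "INV"
    elif form == "t[":
        svtype = "DEL" if mate_pos > pos else "DUP"
    else:  # "]t"
        svtype = "DUP" if mate_pos > pos else "DEL"
    return svtype, mate_contig, mate_pos, abs(mate_pos - pos)


def annotate_sv(raw: RawVariant) -> Optional[SVRecord]:
    """Resolve the SV type and length of one raw row.

    Returns ``None`` for unclassifiable rows (no type information and a
    non-symbolic ALT the same length as REF); callers count these as dropped
    rather than failing, since real caller VCFs contain exotic records.
    """
    info = dict(raw.info)
    svtype = _info_svtype(info)
    mate_contig = mate_pos = None
    bnd_len = None

    symbolic = _SYMBOLIC_RE.match(raw.alt)
    if svtype is None and symbolic:
        token = symbolic.group(1).upper().split(":")[0]
        if token in _KNOWN_TYPES:
            svtype = token
        elif token == "TRA":
            svtype = "CTX"

    if svtype in (None, "BND"):
        classified = _classify_breakend(raw.contig, raw.pos, raw.alt)
        if classified is not None:
            svtype, mate_contig, mate_pos, bnd_len = classified
        elif svtype == "BND":
            return None

    if svtype is None and not symbolic:
        # Sequence-resolved allele: net gain is an insertion, net loss a
        # deletion; equal lengths are unclassifiable here.
        diff = len(raw.alt) - len(raw.ref)
        if diff > 0:
            svtype = "INS"
        elif diff < 0:
            svtype = "DEL"
        else:
            return None
    if svtype is None:
        return None

    svlen: Optional[int] = None
    if info.get("SVLEN") is not None:
        try:
            svlen = abs(int(info["SVLEN"]))
        except (TypeError, ValueError):
            svlen = None
    if svlen is None and bnd_len is not None and svtype != "CTX":
        svlen = bnd_len
    if svlen is None and svtype in ("DEL", "DUP", "INV") and raw.end:
        svlen = raw.end - raw.pos
    if svlen is None and not symbolic and parse_breakend_alt(raw.alt) is None:
        svlen = abs(len(raw.alt) - len(raw.ref))
    if svtype == "CTX":
        svlen = None

    end = raw.end
    if end is None and svlen is not None and svtype in ("DEL", "DUP", "INV"):
        end = raw.pos + svlen
    if mate_pos is not None and mate_contig == raw.contig:
        end = max(raw.pos, mate_pos)

    mate_id = info.get("MATEID")
    if isinstance(mate_id, tuple):
        mate_id = mate_id[0] if mate_id else None
    extra = {
        k: v for k, v in info.items()
        if k not in ("SVTYPE", "SVLEN", "MATEID")
    }
    return SVRecord(
        contig=raw.contig,
        pos=raw.pos,
        svtype=svtype,
        end=end,
        svlen=svlen,
        filter=frozenset(raw.filters) if raw.filters else frozenset(),
        record_id=raw.record_id,
        mate_id=str(mate_id) if mate_id is not None else None,
        mate_contig=mate_contig,
        extra_info=extra,
    )


def annotate_all(
    rows: Sequence[RawVariant], stats: Optional[RefineStats] = None
) -> list[SVRecord]:
    out = []
    dropped = 0
    for raw in rows:
        rec = annotate_sv(raw)
        if rec is None:
            dropped += 1
            logger.warning(
                "dropping unclassifiable record %s:%d (%s)",
                raw.contig, raw.pos, raw.alt,
            )
        else:
            out.append(rec)
    if stats is not None:
        stats.input_rows += len(rows)
        stats.dropped_unclassifiable += dropped
    return out


def filter_min_size(
    records: Sequence[SVRecord],
    cfg: RefineConfig = RefineConfig(),
    stats: Optional[RefineStats] = None,
) -> list[SVRecord]:
    """Drop calls shorter than ``cfg.min_size``; keep calls of unknown length
    (CTX, symbolic INS without a reported SVLEN)."""
    kept = [
        r for r in records if r.svlen is None or r.svlen >= cfg.min_size
    ]
    if stats is not None:
        stats.removed_size += len(records) - len(kept)
    return kept


def _endpoint_like(a: SVRecord, b: SVRecord) -> bool:
    """Whether two records sharing an ID stem plausibly describe the start
    and end of one SV, as opposed to merely carrying sequential IDs.

    Breakend-derived records qualify outright; otherwise the records must
    agree in type and one's position must be the other's end (or one of the
    two must lack a resolved span of its own)."""
    if a.mate_contig or b.mate_contig:
        return True
    if a.svtype != b.svtype:
        return False
    if a.svlen is None or b.svlen is None:
        return True
    return a.end == b.pos or b.end == a.pos


def _pair_links(records: Sequence[SVRecord]):
    """Index groups of records that describe the same SV via paired records."""
    by_id: dict[str, list[int]] = defaultdict(list)
    by_event: dict[str, list[int]] = defaultdict(list)
    by_stem: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        if rec.record_id:
            by_id[rec.record_id].append(i)
            stem = _STEM_RE.match(rec.record_id)
            if stem:
                by_stem[stem.group(1)].append(i)
        event = rec.extra_info.get("EVENT")
        if event is not None:
            by_event[str(event)].append(i)

    parent = list(range(len(records)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    missing_mates = 0
    for i, rec in enumerate(records):
        if rec.mate_id:
            targets = by_id.get(rec.mate_id)
            if targets:
                for j in targets:
                    union(i, j)
            else:
                missing_mates += 1
    for members in by_event.values():
        if len(members) == 2:
            union(*members)
    for members in by_stem.values():
        if len(members) == 2 and _endpoint_like(
            records[members[0]], records[members[1]]
        ):
            union(*members)

    groups: dict[int, set[int]] = defaultdict(set)
    for i in range(len(records)):
        groups[find(i)].add(i)
    linked = [g for g in groups.values() if len(g) > 1]
    return linked, missing_mates


def deduplicate_paired(
    records: Sequence[SVRecord],
    contig_order: Optional[Mapping[str, int]] = None,
    stats: Optional[RefineStats] = None,
) -> list[SVRecord]:
    """Collapse linked start/end record pairs to the start record.

    Within a linked group on one contig the smallest-position record
    survives; across contigs the record on the earliest contig (header order,
    natural-sort fallback) survives.  Unpaired records pass through and the
    input order of survivors is preserved.
    """
    linked, missing_mates = _pair_links(records)
    ckey = contig_sort_key(contig_order)
    drop: set[int] = set()
    for group in linked:
        keep = min(group, key=lambda i: (ckey(records[i].contig),
                                         records[i].pos, i))
        drop.update(group - {keep})
    survivors = [r for i, r in enumerate(records) if i not in drop]
    if stats is not None:
        stats.removed_dedup += len(drop)
        stats.dedup_warnings += missing_mates
    if missing_mates:
        logger.warning("%d mate links point to missing records", missing_mates)
    return survivors


def filter_pass(
    records: Sequence[SVRecord],
    cfg: RefineConfig = RefineConfig(),
    stats: Optional[RefineStats] = None,
) -> list[SVRecord]:
    """Keep calls whose FILTER is exactly PASS (missing filters are not
    retained) unless ``cfg.pass_only`` is off."""
    if not cfg.pass_only:
        return list(records)
    kept = [r for r in records if r.filter == frozenset({"PASS"})]
    if stats is not None:
        stats.removed_filter += len(records) - len(kept)
    return kept


def tag_caller(records: Sequence[SVRecord], caller: str) -> list[SVRecord]:
    """Set every record's caller label (last write wins on re-tagging)."""
    if not caller:
        raise ValueError("caller label must be non-empty")
    return [r.with_caller(caller) for r in records]


def refine_records(
    rows: Sequence[RawVariant],
    caller: str,
    cfg: RefineConfig = RefineConfig(),
    contig_order: Optional[Mapping[str, int]] = None,
) -> tuple[list[SVRecord], RefineStats]:
    """Apply the full annotate → size → dedup → PASS pipeline and tag."""
    stats = RefineStats(caller=caller)
    records = annotate_all(rows, stats)
    records = filter_min_size(records, cfg, stats)
    if cfg.dedup_paired:
        records = deduplicate_paired(records, contig_order, stats)
    records = filter_pass(records, cfg, stats)
    records = tag_caller(records, caller)
    stats.output = len(records)
    logger.info(
        "%s: %d rows -> %d refined (size -%d, dedup -%d, filter -%d)",
        caller, stats.input_rows, stats.output, stats.removed_size,
        stats.removed_dedup, stats.removed_filter,
    )
    return records, stats


def refine_vcf(
    path: str, caller: str, cfg: RefineConfig = RefineConfig()
) -> tuple[list[SVRecord], RefineStats]:
    """Read and refine one caller VCF."""
    rows = read_caller_vcf(path, caller)
    return refine_records(rows, caller, cfg, vcf_contig_order(path))


def summarize_lengths(records: Sequence[SVRecord]) -> dict[str, dict]:
    """Per-type length summaries: count, min, median, max, and IQR.

    The IQR uses linearly interpolated quartiles; the median of an
    even-sized set is the mean of the two central values.  CTX calls are
    reported as a count only, as are types with no length-resolved calls.
    """
    out: dict[str, dict] = {}
    for svtype in ("DEL", "INS", "DUP", "INV", "CTX"):
        of_type = [r for r in records if r.svtype == svtype]
        entry: dict = {"count": len(of_type)}
        lengths = np.array(
            [r.svlen for r in of_type if r.svlen is not None], dtype=float
        )
        if svtype != "CTX" and lengths.size:
            q1, med, q3 = np.percentile(lengths, [25, 50, 75])
            entry.update(
                min=float(lengths.min()),
                median=float(med),
                max=float(lengths.max()),
                iqr=float(q3 - q1),
            )
        out[svtype] = entry
    return out
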