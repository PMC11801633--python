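"""VCF 4.2 reading and writing (pysam/htslib backed).

Reading returns lightweight :class:`RawVariant` rows — one per (record, ALT)
after multi-allelic splitting — which the refinement stage annotates into
:class:`~svensemble.records.SVRecord` objects.  Writing supports two caller
dialects: ``plain`` (symbolic ALT per record) and ``paired`` (DEL/DUP/INV
emitted as two breakend lines linked by MATEID, the start/end record style
some callers produce).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .records import SVRecord, natural_key

# INFO keys consumed by annotation rather than passed through verbatim.
_SPECIAL_INFO = {"SVTYPE", "SVLEN", "END", "MATEID", "EVENT"}

_BND_RE = re.compile(
    r"^(?P<head>[A-Za-z.*]*)"
    r"(?P<open>[\[\]])(?P<contig>[^\[\]:]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<tail>[A-Za-z.*]*)$"
)


@dataclass(frozen=True)
class RawVariant:
    """One VCF data line restricted to a single ALT allele."""

    contig: str
    pos: int
    record_id: Optional[str]
    ref: str
    alt: str
    filters: tuple[str, ...]
    info: Mapping = field(default_factory=dict)
    end: Optional[int] = None
    line_index: int = 0


def parse_breakend_alt(alt: str):
    """Parse a breakend ALT string.

    Returns ``(mate_contig, mate_pos, form)`` where ``form`` encodes the
    junction layout: ``"t["`` (sequence then forward bracket), ``"]t"``,
    ``"t]"`` or ``"[t"``.  Returns ``None`` when the ALT is not breakend
    notation.
    """
    m = _BND_RE.match(alt)
    if not m:
        return None
    head, tail = m.group("head"), m.group("tail")
    bracket = m.group("open")
    if head and not tail:
        form = "t[" if bracket == "[" else "t]"
    elif tail and not head:
        form = "]t" if bracket == "]" else "[t"
    else:
        return None
    return m.group("contig"), int(m.group("pos")), form


def _per_alt(value, alt_index: int, n_alts: int):
    """Positional selection of a possibly list-valued INFO field."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            return value[alt_index]
        return value[0] if value else None
    return value


def read_caller_vcf(path: str, caller: Optional[str] = None) -> list[RawVariant]:
    """Read a caller VCF into raw per-ALT rows.

    Multi-allelic records are split into one row per ALT, with list-valued
    INFO fields (SVLEN etc.) taken positionally when their length matches the
    ALT count and shared otherwise.  Input order is preserved.  A duplicated
    non-missing ID with conflicting coordinates raises ``ValueError`` naming
    the offending record.
    """
    rows: list[RawVariant] = []
    seen_ids: dict[str, tuple[str, int]] = {}
    with pysam.VariantFile(path) as vf:
        for line_index, rec in enumerate(vf):
            alts = rec.alts or ()
            rid = rec.id if rec.id not in (None, ".") else None
            if rid is not None:
                coords = (rec.chrom, rec.pos)
                if rid in seen_ids and seen_ids[rid] != coords:
                    raise ValueError(
                        f"{path}: duplicate ID {rid!r} with conflicting "
                        f"coordinates at record {line_index + 1} "
                        f"({rec.chrom}:{rec.pos} vs "
                        f"{seen_ids[rid][0]}:{seen_ids[rid][1]})"
                    )
                seen_ids[rid] = coords
            info = dict(rec.info)
            # htslib folds END into rec.stop; expose it only when meaningful.
            end = rec.stop if rec.stop and rec.stop > rec.pos else None
            filters = tuple(rec.filter.keys())
            for i, alt in enumerate(alts):
                if alt is None:
                    continue
                alt_info = {
                    k: _per_alt(v, i, len(alts)) for k, v in info.items()
                }
                rows.append(
                    RawVariant(
                        contig=rec.chrom,
                        pos=rec.pos,
                        record_id=rid,
                        ref=rec.ref or "N",
                        alt=str(alt),
                        filters=filters,
                        info=alt_info,
                        end=end,
                        line_index=line_index,
                    )
                )
    return rows


def vcf_contig_order(path: str) -> dict[str, int]:
    """Contig → rank mapping from the VCF header (empty if none declared)."""
    with pysam.VariantFile(path) as vf:
        return {name: i for i, name in enumerate(vf.header.contigs)}


def _build_header(
    records: Sequence[SVRecord],
    contigs: Optional[Sequence[tuple[str, int]]] = None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for svtype in ("DEL", "INS", "DUP", "INV", "CTX"):
        header.add_line(f"##ALT=<ID={svtype},Description=\"{svtype}\">")
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">'
    )
    header.add_line(
        '##INFO=<ID=MATEID,Number=.,Type=String,Description="Mate record">'
    )
    header.add_line(
        '##INFO=<ID=EVENT,Number=1,Type=String,Description="Event ID">'
    )
    header.add_line(
        '##INFO=<ID=caller,Number=.,Type=String,Description="Source callers">'
    )
    header.add_line(
        '##INFO=<ID=SUPP,Number=1,Type=Integer,'
        'Description="Distinct supporting callers">'
    )
    header.add_line(
        '##INFO=<ID=GROUP_SIZE,Number=1,Type=Integer,'
        'Description="Neighbor-group member count">'
    )
    header.add_line(
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Partner contig">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN_UNKNOWN,Number=0,Type=Flag,'
        'Description="Length not reported by the caller">'
    )
    filters = set()
    for rec in records:
        filters.update(rec.filter)
    for name in sorted(filters - {"PASS"}):
        header.add_line(f'##FILTER=<ID={name},Description="{name}">')
    if contigs is None:
        # Infer minimal contig lengths from the records themselves.
        maxima: dict[str, int] = {}
        for rec in records:
            hi = max(rec.pos, rec.end or 0) + 1
            maxima[rec.contig] = max(maxima.get(rec.contig, 0), hi)
            if rec.mate_contig:
                maxima.setdefault(rec.mate_contig, 1)
        contigs = sorted(maxima.items(), key=lambda kv: natural_key(kv[0]))
    for name, length in contigs:
        header.add_line(f"##contig=<ID={name},length={length}>")
    return header


def _new_record(vf, rec: SVRecord, alt: str, rid, stop=None, info=None):
    out = vf.new_record(
        contig=rec.contig,
        start=rec.pos - 1,
        stop=stop if stop is not None else rec.pos,
        alleles=("N", alt),
        id=rid,
    )
    for name in rec.filter or {"PASS"}:
        out.filter.add(name)
    for key, value in (info or {}).items():
        out.info[key] = value
    return out


def write_vcf(
    records: Iterable[SVRecord],
    path: str,
    contigs: Optional[Sequence[tuple[str, int]]] = None,
    dialect: str = "plain",
) -> None:
    """Write records as VCF 4.2.

    ``dialect="paired"`` emits DEL/DUP/INV calls with a known partner
    coordinate as two breakend lines carrying mutual MATEIDs; everything else
    (and the ``plain`` dialect) uses one symbolic-ALT record per call.
    """
    if dialect not in ("plain", "paired"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = list(records)
    header = _build_header(records, contigs)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for k, rec in enumerate(records):
            rid = rec.record_id or f"sv_{k}"
            info = {"SVTYPE": rec.svtype}
            if rec.caller:
                info["caller"] = tuple(rec.caller.split(","))
            for key, value in rec.extra_info.items():
                info[key] = value
            if (
                dialect == "paired"
                and rec.svtype in ("DEL", "DUP", "INV")
                and rec.end is not None
                and rec.end > rec.pos
            ):
                _write_pair(vf, rec, rid, info)
                continue
            if rec.svtype == "CTX":
                if rec.mate_contig:
                    info["CHR2"] = rec.mate_contig
                out = _new_record(vf, rec, "<CTX>", rid, info=info)
            else:
                if rec.svlen is not None:
                    info["SVLEN"] = rec.svlen
                elif rec.svtype == "INS":
                    info["SVLEN_UNKNOWN"] = True
                stop = rec.end if rec.svtype in ("DEL", "DUP", "INV") else None
                out = _new_record(
                    vf, rec, f"<{rec.svtype}>", rid, stop=stop, info=info
                )
            vf.write(out)


# Breakend ALT layout per SV type, for the (lower, upper) coordinate records.
_PAIR_FORMS = {
    "DEL": ("N[{c}:{p}[", "]{c}:{p}]N"),
    "DUP": ("]{c}:{p}]N", "N[{c}:{p}["),
    "INV": ("N]{c}:{p}]", "[{c}:{p}[N"),
}


def _write_pair(vf, rec: SVRecord, rid: str, info: dict) -> None:
    low_alt, high_alt = _PAIR_FORMS[rec.svtype]
    id1, id2 = f"{rid}_1", f"{rid}_2"
    base = {k: v for k, v in info.items() if k != "SVTYPE"}
    first = _new_record(
        vf,
        rec,
        low_alt.format(c=rec.contig, p=rec.end),
        id1,
        info={"SVTYPE": "BND", "MATEID": id2, **base},
    )
    import dataclasses

    upper = dataclasses.replace(rec, pos=rec.end, end=None, svlen=None)
    second = _new_record(
        vf,
        upper,
        high_alt.format(c=rec.contig, p=rec.pos),
        id2,
        info={"SVTYPE": "BND", "MATEID": id1, **base},
    )
    vf.write(first)
    vf.write(second)
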