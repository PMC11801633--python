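"""Refinement stage: annotation, size filter, pair dedup, PASS filter."""

import numpy as np
import pytest

from svensemble.records import RefineConfig, SVRecord
from svensemble.refine import (
    RefineStats,
    annotate_all,
    annotate_sv,
    deduplicate_paired,
    filter_min_size,
    filter_pass,
    refine_records,
    refine_vcf,
    summarize_lengths,
    tag_caller,
)
from svensemble.vcfio import RawVariant, read_caller_vcf, write_vcf


def raw(pos=100, alt="<DEL>", ref="N", contig="chr1", info=None,
        filters=("PASS",), end=None, record_id="r1"):
    return RawVariant(contig=contig, pos=pos, record_id=record_id, ref=ref,
                      alt=alt, filters=tuple(filters), info=info or {},
                      end=end)


class TestReadCallerVcf:
    def test_simple_records_one_row_each(self, make_vcf):
        path = make_vcf(
            "chr1\t100\ta\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=250",
            "chr1\t900\tb\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=80",
            "chr2\t500\tc\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=700",
        )
        rows = read_caller_vcf(path)
        assert len(rows) == 3
        assert [r.pos for r in rows] == [100, 900, 500]

    def test_multiallelic_split(self, make_vcf):
        path = make_vcf(
            "chr1\t100\ta\tN\t<DEL>,<DUP>\t.\tPASS\tEND=300;SVLEN=200,200",
        )
        rows = read_caller_vcf(path)
        assert len(rows) == 2
        assert {r.alt for r in rows} == {"<DEL>", "<DUP>"}

    def test_empty_vcf(self, make_vcf):
        assert read_caller_vcf(make_vcf()) == []

    def test_duplicate_id_conflicting_coordinates(self, make_vcf):
        path = make_vcf(
            "chr1\t100\tdup\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=250",
            "chr1\t999\tdup\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1200",
        )
        with pytest.raises(ValueError, match="dup"):
            read_caller_vcf(path)


class TestAnnotate:
    def test_symbolic_del_end(self):
        out = annotate_sv(raw(pos=100, alt="<DEL>", end=250,
                              info={"SVTYPE": "DEL"}))
        assert (out.svtype, out.svlen) == ("DEL", 150)

    def test_sequence_resolved_insertion(self):
        out = annotate_sv(raw(pos=10, ref="A", alt="A" + "T" * 60))
        assert (out.svtype, out.svlen) == ("INS", 60)

    def test_inter_contig_breakend_is_translocation(self):
        out = annotate_sv(raw(pos=1000, alt="N[chr5:2000[",
                              info={"SVTYPE": "BND"}))
        assert out.svtype == "CTX"
        assert out.svlen is None
        assert out.mate_contig == "chr5"

    @pytest.mark.parametrize(
        "pos,alt,expected",
        [
            # Junction-orientation table for a same-contig pair 1000/4000.
            (1000, "N[chr1:4000[", "DEL"),   # lower end of a deletion
            (4000, "]chr1:1000]N", "DEL"),   # upper end of a deletion
            (1000, "]chr1:4000]N", "DUP"),   # lower end of a tandem dup
            (4000, "N[chr1:1000[", "DUP"),   # upper end of a tandem dup
            (1000, "N]chr1:4000]", "INV"),   # matching-side orientations
            (4000, "[chr1:1000[N", "INV"),
        ],
    )
    def test_breakend_orientation_table(self, pos, alt, expected):
        out = annotate_sv(raw(pos=pos, alt=alt, info={"SVTYPE": "BND"}))
        assert out.svtype == expected
        assert out.svlen == 3000

    def test_info_svtype_has_priority_and_tra_maps_to_ctx(self):
        out = annotate_sv(raw(alt="<DEL>", end=200, info={"SVTYPE": "TRA"}))
        assert out.svtype == "CTX"

    def test_unclassifiable_dropped_with_counter(self):
        rows = [raw(ref="A", alt="C", record_id="snv"),
                raw(alt="<DEL>", end=300)]
        stats = RefineStats()
        records = annotate_all(rows, stats)
        assert len(records) == 1
        assert stats.dropped_unclassifiable == 1

    def test_svlen_absolute_value(self):
        out = annotate_sv(raw(alt="<DEL>", info={"SVTYPE": "DEL",
                                                 "SVLEN": -120}))
        assert out.svlen == 120


class TestSizeFilter:
    @pytest.mark.parametrize("svlen,kept", [(49, False), (50, True)])
    def test_boundary(self, svlen, kept, rec):
        out = filter_min_size([rec(100, svlen=svlen)], RefineConfig())
        assert bool(out) is kept

    def test_ctx_and_unknown_length_kept(self, rec):
        records = [
            SVRecord(contig="chr1", pos=5, svtype="CTX", mate_contig="chr2"),
            SVRecord(contig="chr1", pos=9, svtype="INS", svlen=None),
        ]
        assert filter_min_size(records, RefineConfig()) == records


class TestDeduplicatePaired:
    def test_mate_pair_keeps_smaller_pos(self, rec):
        pair = [
            rec(1000, record_id="a_1", mate_id="a_2"),
            rec(5000, record_id="a_2", mate_id="a_1"),
        ]
        out = deduplicate_paired(pair)
        assert [r.pos for r in out] == [1000]

    def test_unpaired_record_unchanged(self, rec):
        records = [rec(1000, record_id="solo")]
        assert deduplicate_paired(records) == records

    def test_inter_contig_pair_keeps_earlier_contig(self, rec):
        pair = [
            rec(2000, contig="chr5", record_id="b_2", mate_id="b_1"),
            rec(1000, contig="chr1", record_id="b_1", mate_id="b_2"),
        ]
        out = deduplicate_paired(pair, contig_order={"chr1": 0, "chr5": 1})
        assert [(r.contig, r.pos) for r in out] == [("chr1", 1000)]

    def test_missing_mate_counts_warning(self, rec):
        stats = RefineStats()
        records = [rec(1000, record_id="c_1", mate_id="gone")]
        assert deduplicate_paired(records, stats=stats) == records
        assert stats.dedup_warnings == 1

    def test_event_linked_pair(self, rec):
        pair = [
            rec(300, record_id="x", extra_info={"EVENT": "ev9"}),
            rec(900, record_id="y", extra_info={"EVENT": "ev9"}),
        ]
        assert [r.pos for r in deduplicate_paired(pair)] == [300]

    def test_sequential_ids_not_falsely_linked(self, rec):
        # Independent calls whose IDs merely end in _1/_2 must survive.
        records = [
            rec(1000, record_id="call_1", svlen=100),
            rec(50000, record_id="call_2", svlen=700),
        ]
        assert deduplicate_paired(records) == records

    def test_stem_linked_endpoint_pair(self, rec):
        # Start/end records of one SV sharing an ID stem collapse.
        pair = [
            rec(1000, record_id="sv7_1", svlen=4000, end=5000),
            rec(5000, record_id="sv7_2", svlen=None, end=None,
                svtype="DEL"),
        ]
        assert [r.pos for r in deduplicate_paired(pair)] == [1000]

    def test_no_surviving_mate_links(self, rec):
        records = [
            rec(100, record_id="p_1", mate_id="p_2"),
            rec(700, record_id="p_2", mate_id="p_1"),
            rec(5000, record_id="q_1", mate_id="q_2"),
            rec(9000, record_id="q_2", mate_id="q_1"),
        ]
        out = deduplicate_paired(records)
        ids = {r.record_id for r in out}
        assert all(r.mate_id not in ids for r in out)


class TestPassFilter:
    @pytest.mark.parametrize(
        "filters,kept",
        [({"PASS"}, True), ({"LowQual"}, False), (set(), False),
         ({"PASS", "LowQual"}, False)],
    )
    def test_exactly_pass(self, filters, kept, rec):
        records = [rec(100, filter=frozenset(filters))]
        out = filter_pass(records, RefineConfig())
        assert bool(out) is kept

    def test_disabled(self, rec):
        records = [rec(100, filter=frozenset({"LowQual"}))]
        assert filter_pass(records, RefineConfig(pass_only=False)) == records


class TestTagCaller:
    def test_tags_all_and_overwrites(self, rec):
        records = [rec(100, caller="OLD"), rec(900)]
        out = tag_caller(records, "DELLY")
        assert all(r.caller == "DELLY" for r in out)
        assert tag_caller([], "DELLY") == []

    def test_empty_label_rejected(self, rec):
        with pytest.raises(ValueError):
            tag_caller([rec(100)], "")


class TestSummarizeLengths:
    def test_median_and_extremes(self, rec):
        records = [rec(p, svlen=l) for p, l in
                   [(100, 50), (10000, 100), (20000, 150)]]
        out = summarize_lengths(records)["DEL"]
        assert (out["min"], out["median"], out["max"]) == (50, 100, 150)

    def test_even_set_quartiles(self, rec):
        lengths = [50, 100, 150, 1000]
        records = [rec(1000 * i + 1, svlen=l)
                   for i, l in enumerate(lengths)]
        out = summarize_lengths(records)["DEL"]
        # Linear-interpolation quartile convention.
        q1, q3 = np.percentile(lengths, [25, 75])
        assert out["median"] == 125
        assert out["iqr"] == pytest.approx(q3 - q1)

    def test_absent_type_reports_count_only(self, rec):
        out = summarize_lengths([rec(100)])
        assert out["INS"] == {"count": 0}


class TestPipelineInvariants:
    def _random_rows(self, seed, n=60):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            pos = int(rng.integers(1, 1_000_000))
            size = int(rng.integers(10, 5000))
            filt = ("PASS",) if rng.random() < 0.7 else ("LowQual",)
            rows.append(raw(pos=pos, alt="<DEL>", end=pos + size,
                            info={"SVTYPE": "DEL"}, filters=filt,
                            record_id=f"v{i}"))
        return rows

    @pytest.mark.parametrize("seed", range(5))
    def test_refinement_idempotent_and_conserving(self, seed):
        rows = self._random_rows(seed)
        once, stats = refine_records(rows, "X")
        assert stats.input_rows - stats.output == (
            stats.dropped_unclassifiable + stats.removed_size
            + stats.removed_dedup + stats.removed_filter
        )
        cfg = RefineConfig()
        again = filter_pass(
            deduplicate_paired(filter_min_size(once, cfg)), cfg)
        assert again == once

    def test_roundtrip_preserves_fields(self, tmp_path, rec):
        rng = np.random.default_rng(7)
        records = []
        for i in range(40):
            svtype = str(rng.choice(["DEL", "INS", "DUP", "INV"]))
            records.append(rec(
                int(rng.integers(1, 900_000)), svtype=svtype,
                svlen=int(rng.integers(50, 9000)),
                caller="X", record_id=f"rt{i}",
            ))
        records.sort(key=lambda r: r.pos)
        path = str(tmp_path / "rt.vcf")
        write_vcf(records, path, contigs=[("chr1", 1_000_000)])
        back, _ = refine_vcf(path, "X")
        assert [(r.contig, r.pos, r.svtype, r.svlen, r.caller)
                for r in back] == \
               [(r.contig, r.pos, r.svtype, r.svlen, r.caller)
                for r in records]
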