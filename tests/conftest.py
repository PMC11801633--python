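import textwrap

import pytest

from svensemble.records import SVRecord

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000000>
    ##contig=<ID=chr2,length=100000000>
    ##contig=<ID=chr5,length=100000000>
    ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
    ##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="x">
    ##INFO=<ID=END,Number=1,Type=Integer,Description="x">
    ##INFO=<ID=MATEID,Number=.,Type=String,Description="x">
    ##INFO=<ID=EVENT,Number=1,Type=String,Description="x">
    ##FILTER=<ID=LowQual,Description="x">
    ##FILTER=<ID=q5,Description="x">
    ##ALT=<ID=DEL,Description="x">
    ##ALT=<ID=DUP,Description="x">
    ##ALT=<ID=INS,Description="x">
    ##ALT=<ID=INV,Description="x">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    """)


@pytest.fixture
def make_vcf(tmp_path):
    """Write a hand-authored VCF from data lines; returns the path."""
    counter = {"n": 0}

    def _make(*lines, header=VCF_HEADER):
        counter["n"] += 1
        path = tmp_path / f"fixture{counter['n']}.vcf"
        path.write_text(header + "".join(line + "\n" for line in lines))
        return str(path)

    return _make


@pytest.fixture
def rec():
    """Factory for SVRecord with terse defaults."""

    def _rec(pos, svtype="DEL", contig="chr1", svlen=100, caller=None,
             **kwargs):
        end = kwargs.pop("end", None)
        if end is None and svtype in ("DEL", "DUP", "INV") and svlen:
            end = pos + svlen
        return SVRecord(contig=contig, pos=pos, svtype=svtype, end=end,
                        svlen=svlen, caller=caller, **kwargs)

    return _rec
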