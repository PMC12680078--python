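import pytest

from pepgraph.caller import CallParams
from pepgraph.gvf import VariantRecord


@pytest.fixture
def params():
    return CallParams()


def make_snv(pos, ref, alt, vid="v1", **kw):
    defaults = dict(
        gene_id="G1",
        transcript_ids=("T1",),
        start_tx=pos,
        end_tx=pos + 1,
        ref_seq=ref,
        alt_seq=alt,
        type="SNV",
        source="sSNV",
        variant_id=vid,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


def make_indel(pos, ref, alt, vid="v1", **kw):
    vtype = "INSERTION" if len(alt) > len(ref) else "DELETION"
    defaults = dict(
        gene_id="G1",
        transcript_ids=("T1",),
        start_tx=pos,
        end_tx=pos + len(ref),
        ref_seq=ref,
        alt_seq=alt,
        type=vtype,
        source="sIndel",
        variant_id=vid,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


def make_alt_splice(pos, ref, alt, vid="as1", vtype="ALT_SPLICE_RI", **kw):
    defaults = dict(
        gene_id="G1",
        transcript_ids=("T1",),
        start_tx=pos,
        end_tx=pos + len(ref),
        ref_seq=ref,
        alt_seq=alt,
        type=vtype,
        source="AltSplice",
        variant_id=vid,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)
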