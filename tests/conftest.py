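import numpy as np
import pandas as pd
import pytest

from herbclock.io_core import SampleMeta, VariantTable


def make_variant_table(calls, classes=None, samples=None, accessible=None,
                      positions=None, chrom="1"):
    """Build a VariantTable from a (sites x samples) array of 0/1/-1 calls."""
    calls = np.asarray(calls, dtype=np.int8)
    S, n = calls.shape
    samples = samples or [f"s{i}" for i in range(n)]
    classes = classes if classes is not None else ["intergenic"] * S
    positions = positions if positions is not None else np.arange(1, S + 1) * 10
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "anc": "A", "der": "T",
         "annotation_class": classes}
    )
    return VariantTable(sites, calls, list(samples), dict(accessible or {}))


def make_meta(samples, years, eras, lat=40.0, lon=-85.0):
    return [
        SampleMeta(s, int(y), lat, lon, e)
        for s, y, e in zip(samples, years, eras)
    ]


@pytest.fixture
def toy_vcf(tmp_path):
    """3-site, 2-sample haploid VCF; all calls derived."""
    text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t1\t1\n"
        "1\t20\t.\tC\tG\t.\tPASS\t.\tGT\t1\t1\n"
        "1\t30\t.\tG\tA\t.\tPASS\t.\tGT\t1\t1\n"
    )
    p = tmp_path / "toy.vcf"
    p.write_text(text)
    return p


@pytest.fixture
def toy_meta():
    return make_meta(["S1", "S2"], [1900, 2000], ["herbarium", "modern"])
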