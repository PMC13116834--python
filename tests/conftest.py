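import textwrap

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

#: Fixed seed for all deterministic randomized tests.
SEED = 20317


VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=1>
    ##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
    ##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence term">
    ##INFO=<ID=POP_AF,Number=A,Type=Float,Description="Population allele frequency">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    """
)


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write a small hand-rolled VCF and return its path."""

    def _write(body: str, samples: list[str], name: str = "mini.vcf"):
        path = tmp_path / name
        header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
        path.write_text(header + textwrap.dedent(body))
        return path

    return _write
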