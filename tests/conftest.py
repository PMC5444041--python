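import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def write_vcf(tmp_path):
    """Factory writing a minimal VCF from (chrom, pos, id, ref, alt, info, gts) rows."""

    def _write(rows, samples, name="test.vcf"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=FUNC,Number=1,Type=String,Description="x">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n')
            chroms = sorted({r[0] for r in rows})
            for c in chroms:
                fh.write(f"##contig=<ID={c},length=1000000>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples)
                + "\n"
            )
            for chrom, pos, vid, ref, alt, info, gts in rows:
                fh.write(
                    f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t{info}\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )
        return path

    return _write
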