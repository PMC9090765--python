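import pytest

from parpomics.genome import ChromosomeInfo, GenomeBuild, load_genome_build
from parpomics.model import Segment, SegmentProfile
from parpomics.signatures import synthetic_reference


@pytest.fixture(scope="session")
def toy_build():
    return load_genome_build("toy")


@pytest.fixture(scope="session")
def hg_build():
    return load_genome_build("hg19-like")


@pytest.fixture(scope="session")
def mini_build():
    """10 Mb chromosomes: small enough for the per-base wGII oracle."""
    chroms = [
        ChromosomeInfo("1", 10_000_000, 4_000_000, 5_000_000),
        ChromosomeInfo("2", 10_000_000, 4_000_000, 5_000_000),
        ChromosomeInfo("3", 10_000_000, 4_000_000, 5_000_000),
    ]
    return GenomeBuild(chroms, acrocentric_p_arms={"3"}, name="mini")


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference(4)


def make_profile(segs, sample_id="t"):
    """Shorthand: segs = [(chrom, start, end, major, minor), ...]."""
    return SegmentProfile(
        sample_id, [Segment(c, s, e, M, m) for c, s, e, M, m in segs]
    )
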