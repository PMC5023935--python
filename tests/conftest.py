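import numpy as np
import pytest

from varconcord import analyze_bundle, build_paper_fixture
from varconcord.gene_models import GeneModel


@pytest.fixture(scope="session")
def fixture_bundle():
    """The deterministic 391-variant study fixture (built once)."""
    return build_paper_fixture(seed=20160510)


@pytest.fixture(scope="session")
def fixture_result(fixture_bundle):
    return analyze_bundle(fixture_bundle)


@pytest.fixture(scope="session")
def fixture_dir(fixture_bundle, tmp_path_factory):
    """The fixture written to disk once, for file-based and CLI tests."""
    from varconcord.synthetic import write_bundle

    out = tmp_path_factory.mktemp("fixture_bundle")
    write_bundle(fixture_bundle, out)
    return out


@pytest.fixture
def plus_model():
    """Two-exon plus-strand transcript with UTRs on both ends."""
    return GeneModel(
        gene_name="TOYP",
        chrom="chrT",
        strand="+",
        exons=((100, 160), (220, 300)),
        cds_start=110,
        cds_end=280,
    )


@pytest.fixture
def minus_model():
    """Two-exon minus-strand transcript with UTRs on both ends."""
    return GeneModel(
        gene_name="TOYM",
        chrom="chrT",
        strand="-",
        exons=((100, 160), (220, 300)),
        cds_start=110,
        cds_end=280,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231118)


def random_model(rng, strand=None, chrom="chrF"):
    """Fuzz helper: a random multi-exon transcript with CDS."""
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(30, 120))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(8, 60))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(25, 90))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    span_start, span_end = exons[0][0], exons[-1][1]
    cds_start = int(rng.integers(span_start, span_start + (exons[0][1] - exons[0][0])))
    cds_end = int(rng.integers(exons[-1][0] + 1, span_end + 1))
    if cds_end <= cds_start:
        cds_start, cds_end = span_start, span_end
    return GeneModel(
        gene_name="FUZZ",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )
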