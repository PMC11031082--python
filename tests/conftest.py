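import numpy as np
import pytest

from hfs.segmentation import Locus


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def fixture_cohort(tmp_path_factory):
    """Toy on-disk cohort (FASTA, phased VCF, state BEDs, phenotype)."""
    from hfs.simulate import generate_fixture_cohort

    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_fixture_cohort(out, seed=11)
    return out, manifest


def make_loci(windows, chrom="chr1", origin="gap_fill"):
    return [Locus(f"{chrom}:{s}-{e}", chrom, s, e, origin) for s, e in windows]
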