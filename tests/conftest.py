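import numpy as np
import pytest

from pepatlas.synthetic import (
    SyntheticComplexSpec,
    make_backbone_family,
    make_complex,
    synthetic_reference_alleles,
    write_reference_fasta,
)


@pytest.fixture(scope="session")
def references():
    return synthetic_reference_alleles()


@pytest.fixture(scope="session")
def reference_fasta(references, tmp_path_factory):
    path = tmp_path_factory.mktemp("refs") / "alleles.fasta"
    write_reference_fasta(path, references)
    return path


@pytest.fixture(scope="session")
def toy_complex_dir(references, tmp_path_factory):
    """Directory of accept-able toy complexes with varied seeds and dates."""
    d = tmp_path_factory.mktemp("raw")
    for k, (seed, date) in enumerate(
        [(1, "2005-03-01"), (2, "2005-07-15"), (3, "2012-02-02"), (4, "2019-11-30")]
    ):
        spec = SyntheticComplexSpec(
            pdb_id=f"TOY{k}", seed=seed, phi_std=4.0, psi_std=4.0,
            release_date=date,
        )
        make_complex(spec, out_path=d / f"TOY{k}.pdb")
    return d


@pytest.fixture(scope="session")
def ppii_family():
    return make_backbone_family(8, center=(-75.0, 145.0), spread=1.5, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
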