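import pytest

from dnajsurvey import formats_io, synthetic_data


@pytest.fixture(scope="session")
def catalog():
    return formats_io.load_catalog_fixture()


@pytest.fixture(scope="session")
def small_design():
    return synthetic_data.SimulationDesign(
        seed=11, n_family_genes=15, n_decoys=3, n_chromosomes=3, n_tandem_pairs=1
    )


@pytest.fixture(scope="session")
def small_bundle(small_design):
    return synthetic_data.simulate(small_design)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle_small")
    small_bundle.write(outdir)
    return outdir


@pytest.fixture(scope="session")
def study_bundle():
    """A design mirroring the surveyed family: 76 members in group
    proportions 9/8/53/1/5, 9 incomplete-J decoys, one tandem pair."""
    return synthetic_data.simulate(synthetic_data.SimulationDesign(seed=5))


@pytest.fixture(scope="session")
def study_members(study_bundle):
    from dnajsurvey.domain_annotation import ArchitectureConfig
    from dnajsurvey.formats_io import GeneRecord
    from dnajsurvey.report import build_members

    import io

    genes = _genes_from_gff_text(study_bundle.gff3)
    members, removed, archs = build_members(
        study_bundle.proteome,
        genes,
        study_bundle.domain_hits,
        ArchitectureConfig(),
        prefix="SimDnaJ",
    )
    return members, removed


def _genes_from_gff_text(text):
    import tempfile

    from dnajsurvey.formats_io import read_gff3

    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(text)
        path = fh.name
    return read_gff3(path)


@pytest.fixture(scope="session")
def gff_loader():
    return _genes_from_gff_text
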