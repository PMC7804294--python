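import pytest

from riboarch import synthetic
from riboarch.network import graph_from_contact_table

STUDY_SEED = 0


@pytest.fixture(scope="session")
def study():
    """Default planted network study (the study conditions)."""
    return synthetic.make_annotated_network(
        synthetic.NetworkStudySpec(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def kingdom_graphs(study):
    return {stage: graph_from_contact_table(study.tables[stage], stage,
                                            coords=study.coords,
                                            subunits=study.subunits)
            for stage in synthetic.STAGES}


@pytest.fixture(scope="session")
def msa_fixture():
    return synthetic.make_msa(synthetic.MsaSpec(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("toys")


@pytest.fixture(scope="session")
def kissing_pair(toy_dir):
    """Two helices in surface contact (gap ~1 A)."""
    return synthetic.two_helix_complex(1.0, toy_dir, n_residues=11)


@pytest.fixture(scope="session")
def separated_pair(toy_dir):
    """Two helices 50 A apart: no burial possible."""
    return synthetic.two_helix_complex(50.0, toy_dir, n_residues=11)
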