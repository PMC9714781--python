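import pytest

import clonetracer as ct


@pytest.fixture(scope="session")
def lambda_ref():
    """Lambda-locus germline scaffolds (4 POEMS families + 2 J alleles)."""
    return ct.build_germline_reference(seed=1)


@pytest.fixture(scope="session")
def full_ref():
    """Lambda plus heavy-chain scaffolds."""
    return ct.build_germline_reference(seed=1) + ct.build_germline_reference(
        v_count=3, seed=8, locus="IGH"
    )


@pytest.fixture(scope="session")
def clean_cohort(full_ref):
    """60 cells, 20% planted clone, no sequencing error, both chains."""
    cfg = ct.SimulationConfig(
        n_cells=60, clone_fraction=0.2, per_base_error_rate=0.0, seed=5
    )
    return ct.simulate_repertoire(cfg, full_ref)


@pytest.fixture(scope="session")
def clean_annotations(clean_cohort):
    return ct.annotate_cohort(clean_cohort)
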