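import pytest

from mitocomp.annotation_io import load_reference_annotation
from mitocomp.synthetic_data import SyntheticGenomeSpec, generate_genome, table2_mirror_spec


@pytest.fixture(scope="session")
def reference_record():
    """The packaged C. meridianus annotation table (no sequence)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def default_genome():
    """Ancestral-order synthetic genome, zero spacers, composition defaults."""
    return generate_genome(SyntheticGenomeSpec(seed=1))


@pytest.fixture(scope="session")
def mirror_genome():
    """Synthetic genome whose layout mirrors the reference annotation
    (observed gene order and every printed signed spacer)."""
    return generate_genome(table2_mirror_spec(seed=2))
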