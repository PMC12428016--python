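import pytest

from mitoray import reference, simulate
from mitoray.annotation import validate_annotation


@pytest.fixture(scope="session")
def leopoldi():
    """The packaged organization-table record (annotation-only)."""
    return reference.leopoldi_record()


@pytest.fixture(scope="session")
def leopoldi_report(leopoldi):
    return validate_annotation(leopoldi)


@pytest.fixture(scope="session")
def synthetic_genome():
    """Default synthetic mitogenome with its ground truth (fixed seed)."""
    return simulate.generate_genome(seed=7)


@pytest.fixture(scope="session")
def printed():
    return reference.printed_values()
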