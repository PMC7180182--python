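import pytest

from pptscreen import (
    allocate_antibody_flags,
    reconstruct_reference_cohort,
    reference_constraints,
)


@pytest.fixture(scope="session")
def reference_cohort():
    """The 412-woman reconstruction, antibody flags unset."""
    return reconstruct_reference_cohort()


@pytest.fixture(scope="session")
def flagged_cohort():
    """The reconstruction with constraint-calibrated antibody flags."""
    return allocate_antibody_flags(
        reconstruct_reference_cohort(), reference_constraints()
    )
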