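import itertools

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


from oligoscore.model import (  # noqa: E402
    ControlEvidence,
    ControlSource,
    SharedVariantRole,
)


def enumerate_control_evidence():
    """Every statistical-evidence configuration: all sources x all boolean
    settings x with/without a shared-variant support flag."""
    bools = list(itertools.product([False, True], repeat=6))
    for source in ControlSource:
        for expl, size, eth, phen, seq, absent in bools:
            for shared in (frozenset(), frozenset({SharedVariantRole.MODIFIER_ROLE})):
                yield ControlEvidence(
                    source=source,
                    explicit=expl,
                    size_sufficient=size,
                    ethnicity_matched=eth,
                    phenotypes_known=phen,
                    sequencing_similar=seq,
                    combination_absent=absent,
                    shared_variant_support=shared,
                )


@pytest.fixture(scope="session")
def worked_examples():
    from oligoscore.examples import packaged_worked_examples

    return packaged_worked_examples()
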