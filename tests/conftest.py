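import pytest
from hypothesis import settings

import benfordeco as b

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

CASE_NAMES = [
    "succession_early",
    "succession_late",
    "diatoms_small",
    "diatoms_large",
    "salamanders_pre1990",
    "salamanders_post1990",
    "fish_ewh",
    "combined_steady_state",
]

#: The seven individual case comparisons (the pooled tally excluded),
#: in summary-table row order.
SUMMARY_CASES = CASE_NAMES[:-1]


@pytest.fixture(scope="session")
def fixtures():
    return {name: b.load_case(name) for name in CASE_NAMES}


@pytest.fixture(scope="session")
def reports(fixtures):
    return {name: b.conformity_report(fix.tally) for name, fix in fixtures.items()}
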