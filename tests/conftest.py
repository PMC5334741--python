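import pytest

from ifpr_consensus import case_study_panel


@pytest.fixture(scope="session")
def case_panel():
    """The built-in grass-carp cooking-method panel (m=3, n=4)."""
    return case_study_panel()
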