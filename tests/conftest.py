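import pytest

from dkdcea import default_inputs


@pytest.fixture(scope="session")
def base():
    """Packaged base-case input set (session-wide, treated as read-only)."""
    return default_inputs()
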