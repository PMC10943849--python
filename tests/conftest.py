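import pytest

from pcbdechlor.simulate import write_fixture_study


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """A complete miniature synthetic study on disk (seed 1)."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = write_fixture_study(outdir, seed=1)
    return cfg
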