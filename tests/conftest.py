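import pytest

import hornscan as hs


@pytest.fixture(scope="session")
def allele_fixture():
    """Default multiplex-PCR allele templates and primers (fixed seed)."""
    templates, primers = hs.synth_allele_sequences(hs.AssayFixtureParams(seed=0))
    return templates, primers


@pytest.fixture(scope="session")
def scan_matrix():
    """Default-condition case/control scan matrix (fixed seed)."""
    return hs.simulate_scan_data(hs.ScanSimParams(seed=7))
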