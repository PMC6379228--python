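import pytest

import genemeta as gm


@pytest.fixture(scope="session")
def fixture_ds() -> gm.Dataset:
    return gm.load_fixture()


@pytest.fixture(scope="session")
def fas670(fixture_ds) -> gm.Dataset:
    return fixture_ds.for_snp("-670 A/G")


@pytest.fixture(scope="session")
def fixture_report(fixture_ds) -> gm.AnalysisReport:
    """Full pipeline run on the packaged dataset (computed once)."""
    return gm.run_analysis(fixture_ds)
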