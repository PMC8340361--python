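import pytest

from metstop import datasets
from metstop.sites import SiteWindows


@pytest.fixture(scope="session")
def domain_records():
    return datasets.load_px_domain_table()


@pytest.fixture(scope="session")
def ptm_records():
    return datasets.load_ptm_site_table()


@pytest.fixture(scope="session")
def by_name(domain_records):
    return {r.name: r for r in domain_records}


@pytest.fixture()
def toy_windows():
    # 20-column toy alignment: sites cover columns 3-6, 9-11 and 14-17
    return SiteWindows(site1=(3, 6), site2=(9, 11), site3=(14, 17))
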