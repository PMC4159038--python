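import io

import pytest

from eihe.guilds import GuildDefinition, GuildGenus, default_guild
from eihe.io import read_mothur_tax_summary

TOY_TAX_SUMMARY = """taxlevel\trankID\ttaxon\tdaughterlevels\ttotal\tS1
0\t0\tRoot\t3\t1000\t1000
1\t0.1\tAlcanivorax\t0\t30\t30
1\t0.2\tMarinobacter\t0\t20\t20
1\t0.3\tOther\t0\t950\t950
"""

TWO_SAMPLE_TAX_SUMMARY = """taxlevel\trankID\ttaxon\tdaughterlevels\ttotal\tpolluted\tpristine
0\t0\tRoot\t3\t50000\t25000\t25000
1\t0.1\tAlcanivorax\t0\t1200\t1100\t100
1\t0.2\tMarinobacter\t0\t350\t200\t150
1\t0.3\tOther\t0\t48450\t23700\t24750
"""


@pytest.fixture
def toy_table():
    return read_mothur_tax_summary(io.StringIO(TOY_TAX_SUMMARY))


@pytest.fixture
def two_sample_table():
    return read_mothur_tax_summary(io.StringIO(TWO_SAMPLE_TAX_SUMMARY))


@pytest.fixture(scope="session")
def guild63():
    return default_guild()


@pytest.fixture
def small_guild():
    return GuildDefinition(
        name="toy",
        version="1.0",
        entries=(
            GuildGenus(genus_name="Alcanivorax", phylum="Proteobacteria"),
            GuildGenus(genus_name="Marinobacter", phylum="Proteobacteria"),
        ),
    )
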