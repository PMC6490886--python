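import pytest

from pksdecode import assembly_line as al
from pksdecode import cluster_io as cio
from pksdecode.domain_grammar import load_profiles


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def oss_cluster():
    return cio.ossamycin_cluster()


@pytest.fixture(scope="session")
def oss_roles(oss_cluster):
    return cio.classify_roles(oss_cluster)


@pytest.fixture(scope="session")
def oss_tables():
    return al.ossamycin_call_tables()


@pytest.fixture(scope="session")
def oss_target():
    return al.ossamycin_target()


@pytest.fixture(scope="session")
def oss_module_table(oss_tables):
    return al.build_modules(oss_tables)


@pytest.fixture(scope="session")
def oss_ordering(oss_module_table, oss_target):
    return al.order_multienzymes(oss_module_table, oss_target)


@pytest.fixture(scope="session")
def oss_modules_in_order(oss_module_table, oss_ordering):
    return [
        m
        for pid in oss_ordering.order
        for m in oss_module_table.modules_by_protein[pid]
        if not m.malformed
    ]
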