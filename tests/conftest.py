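from pathlib import Path

import pytest

from unitlink.lookup import Resolver
from unitlink.resources import (
    data_path,
    default_pseudo_rules,
    default_qudt_rules,
    default_vocabulary,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def pseudo_rules():
    return default_pseudo_rules()


@pytest.fixture(scope="session")
def qudt_rules():
    return default_qudt_rules()


@pytest.fixture(scope="session")
def resolver(vocab, pseudo_rules, qudt_rules):
    return Resolver(vocab, pseudo_rules, qudt_rules)


@pytest.fixture(scope="session")
def example_eml_path():
    return str(data_path("example_eml.xml"))


@pytest.fixture(scope="session")
def label_manifest():
    lines = (DATA_DIR / "label_roundtrip_manifest.txt").read_text().splitlines()
    return [l.strip() for l in lines if l.strip() and not l.startswith("#")]
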