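"""Access to the bundled default vocabulary, rule sets and schema."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .rules import RuleSet, load_rules
from .vocab import UnitVocabulary, load_vocabulary

__all__ = [
    "data_path",
    "default_vocabulary",
    "default_pseudo_rules",
    "default_qudt_rules",
]

_DATA = resources.files("unitlink") / "data"


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    path = Path(str(_DATA / name))
    if not path.is_file():
        raise FileNotFoundError(f"no bundled data file {name!r}")
    return path


def default_vocabulary() -> UnitVocabulary:
    """The bundled QUDT v2.1.25 snapshot subset."""
    return load_vocabulary(data_path("qudt_units_snapshot.csv"))


def default_pseudo_rules() -> RuleSet:
    return load_rules(data_path("pseudo_rules.csv"), phase="pseudo")


def default_qudt_rules() -> RuleSet:
    return load_rules(data_path("qudt_rules.csv"), phase="qudt")
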