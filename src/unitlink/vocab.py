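"""QUDT unit vocabulary: unit records, dimension vectors, SI conversion data.

The QUDT ontology assigns every unit a *dimension vector* — exponents over
eight basis dimensions (amount of substance, electric current, length,
luminous intensity, mass, thermodynamic temperature, time, and a dimensionless
placeholder) — plus a multiplier (and optional offset) to the coherent SI
unit.  Exact equality of dimension vectors is what licenses direct value
conversion, so exponents are stored as exact rationals, never floats.

The vocabulary is loaded from a flat snapshot table (one row per unit); an
offline Turtle importer (:mod:`unitlink.ttl_import`) can regenerate such a
snapshot from an official QUDT release.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "DIMENSION_LETTERS",
    "DimensionVector",
    "QudtUnit",
    "UnitVocabulary",
    "VocabularyError",
    "parse_dimension_vector",
    "load_vocabulary",
    "find_by_ucum",
]

#: Fixed letter order of the eight QUDT basis dimensions:
#: amount of substance, electric current, length, luminous intensity,
#: mass, thermodynamic temperature, time, dimensionless.
DIMENSION_LETTERS = ("A", "E", "L", "I", "M", "H", "T", "D")

_FIELD_BY_LETTER = {
    "A": "amount_of_substance",
    "E": "electric_current",
    "L": "length",
    "I": "luminous_intensity",
    "M": "mass",
    "H": "thermodynamic_temperature",
    "T": "time",
    "D": "dimensionless",
}


class VocabularyError(ValueError):
    """Raised for malformed snapshot tables or invariant violations."""


@dataclass(frozen=True)
class DimensionVector:
    """Exponents over the eight QUDT basis dimensions (exact rationals)."""

    amount_of_substance: Fraction = Fraction(0)
    electric_current: Fraction = Fraction(0)
    length: Fraction = Fraction(0)
    luminous_intensity: Fraction = Fraction(0)
    mass: Fraction = Fraction(0)
    thermodynamic_temperature: Fraction = Fraction(0)
    time: Fraction = Fraction(0)
    dimensionless: Fraction = Fraction(0)

    def exponents(self) -> tuple[Fraction, ...]:
        """Exponents in canonical letter order A, E, L, I, M, H, T, D."""
        return tuple(getattr(self, _FIELD_BY_LETTER[c]) for c in DIMENSION_LETTERS)

    def render(self) -> str:
        """Canonical QUDT-style notation, e.g. ``A0E0L1I0M0H0T-2D0``.

        Halves use the QUDT ``dot`` convention (``T-0dot5``).
        """
        parts = []
        for letter, expo in zip(DIMENSION_LETTERS, self.exponents()):
            parts.append(letter + _render_exponent(expo))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _render_exponent(x: Fraction) -> str:
    sign = "-" if x < 0 else ""
    x = abs(x)
    if x.denominator == 1:
        return sign + str(x.numerator)
    whole, rem = divmod(x.numerator, x.denominator)
    # decimal expansion must terminate (QUDT uses halves only)
    digits = ""
    num = rem
    den = x.denominator
    while num:
        num *= 10
        d, num = divmod(num, den)
        digits += str(d)
        if len(digits) > 12:
            raise VocabularyError(f"non-terminating exponent {x}")
    return f"{sign}{whole}dot{digits}"


_EXPONENT_RE = re.compile(r"(-?)(\d+)(?:dot(\d+))?")


def parse_dimension_vector(text: str) -> DimensionVector:
    """Parse canonical QUDT dimension-vector notation.

    The notation lists all eight letters in the fixed order
    ``A,E,L,I,M,H,T,D``, each followed by a signed rational exponent
    (integer, or halves written with ``dot``, e.g. ``0dot5``).
    ``render(parse(t)) == t`` for canonical inputs.
    """
    pos = 0
    values: dict[str, Fraction] = {}
    for letter in DIMENSION_LETTERS:
        if pos >= len(text) or text[pos] != letter:
            raise VocabularyError(
                f"dimension vector {text!r}: expected letter {letter!r} at "
                f"position {pos}"
            )
        pos += 1
        m = _EXPONENT_RE.match(text, pos)
        if not m:
            raise VocabularyError(
                f"dimension vector {text!r}: unparseable exponent after "
                f"{letter!r}"
            )
        sign, whole, frac = m.groups()
        value = Fraction(int(whole))
        if frac:
            value += Fraction(int(frac), 10 ** len(frac))
        if sign:
            value = -value
        values[letter] = value
        pos = m.end()
    if pos != len(text):
        raise VocabularyError(f"dimension vector {text!r}: trailing text {text[pos:]!r}")
    return DimensionVector(**{_FIELD_BY_LETTER[k]: v for k, v in values.items()})


@dataclass(frozen=True)
class QudtUnit:
    """One QUDT unit record.

    ``si_multiplier``/``si_offset`` convert a value to the coherent SI unit:
    ``si_value = si_multiplier * value + si_offset``.  Units lacking a
    published dimension vector or multiplier carry ``None`` there; conversion
    involving them raises rather than inventing factors.
    """

    code: str
    uri: str
    label: str
    dimension_vector: DimensionVector | None = None
    si_multiplier: float | None = None
    si_offset: float = 0.0
    ucum_codes: tuple[str, ...] = ()
    quantity_kinds: tuple[str, ...] = ()
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.code or re.search(r"\s", self.code):
            raise VocabularyError(f"invalid unit code {self.code!r}")
        if not self.uri.endswith(self.code):
            raise VocabularyError(
                f"unit {self.code}: URI {self.uri!r} does not end with the code"
            )
        if self.si_multiplier is not None and not self.si_multiplier > 0:
            raise VocabularyError(
                f"unit {self.code}: si_multiplier must be positive, "
                f"got {self.si_multiplier}"
            )


class UnitVocabulary:
    """Units indexed by code, with a secondary UCUM-alias index."""

    def __init__(self, units: Iterable[QudtUnit], version: str = "") -> None:
        self._by_code: dict[str, QudtUnit] = {}
        for unit in units:
            if unit.code in self._by_code:
                raise VocabularyError(f"duplicate unit code {unit.code!r}")
            self._by_code[unit.code] = unit
        self._by_ucum: dict[str, list[str]] = {}
        for unit in self._by_code.values():
            for ucum in unit.ucum_codes:
                self._by_ucum.setdefault(ucum, []).append(unit.code)
        self.version = version

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self):
        return iter(self._by_code.values())

    def get(self, code: str) -> QudtUnit | None:
        return self._by_code.get(code)

    def __getitem__(self, code: str) -> QudtUnit:
        return self._by_code[code]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._by_code)

    @property
    def ucum_index(self) -> Mapping[str, list[str]]:
        return self._by_ucum


def find_by_ucum(vocab: UnitVocabulary, ucum: str) -> list[QudtUnit]:
    """All units whose UCUM aliases contain *ucum* (exact, case-sensitive).

    UCUM is case-sensitive, so no folding is applied.  An empty result is an
    empty list, never an error.
    """
    return [vocab[c] for c in vocab.ucum_index.get(ucum, [])]


_REQUIRED_COLUMNS = (
    "code",
    "uri",
    "label",
    "dimension_vector",
    "si_multiplier",
    "si_offset",
    "ucum",
    "quantity_kinds",
    "description",
)


def load_vocabulary(path: str | Path, format: str = "snapshot_table") -> UnitVocabulary:
    """Load a unit vocabulary from a flat snapshot table.

    The snapshot is UTF-8 delimited text with a header row and columns
    ``code, uri, label, dimension_vector, si_multiplier, si_offset, ucum,
    quantity_kinds, description``; multi-valued cells are
    semicolon-separated; lines starting with ``#`` are comments.  The
    optional ``version`` is carried on a ``#version:`` comment line.
    Duplicate codes are an error, not silently merged.
    """
    if format != "snapshot_table":
        raise VocabularyError(
            f"unsupported format {format!r}; use the Turtle importer to "
            "produce a snapshot_table first"
        )
    path = Path(path)
    if not path.is_file():
        raise VocabularyError(f"vocabulary file not found: {path}")
    text = path.read_text(encoding="utf-8")
    version = ""
    data_lines = []
    for line in text.splitlines():
        if line.lstrip().startswith("#"):
            stripped = line.lstrip().lstrip("#").strip()
            if stripped.lower().startswith("version:"):
                version = stripped.split(":", 1)[1].strip()
            continue
        if line.strip():
            data_lines.append(line)
    reader = csv.DictReader(io.StringIO("\n".join(data_lines)))
    if reader.fieldnames is None:
        return UnitVocabulary([], version=version)
    missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise VocabularyError(f"snapshot table missing required columns: {missing}")
    units = []
    for i, row in enumerate(reader, start=2):
        try:
            units.append(_unit_from_row(row))
        except VocabularyError as exc:
            raise VocabularyError(f"{path}:{i}: {exc}") from None
    return UnitVocabulary(units, version=version)


def _unit_from_row(row: Mapping[str, str]) -> QudtUnit:
    def cell(name: str) -> str:
        return (row.get(name) or "").strip()

    dim_text = cell("dimension_vector")
    mult_text = cell("si_multiplier")
    offset_text = cell("si_offset")
    try:
        multiplier = float(mult_text) if mult_text else None
    except ValueError:
        raise VocabularyError(f"unparseable si_multiplier {mult_text!r}")
    try:
        offset = float(offset_text) if offset_text else 0.0
    except ValueError:
        raise VocabularyError(f"unparseable si_offset {offset_text!r}")
    return QudtUnit(
        code=cell("code"),
        uri=cell("uri"),
        label=cell("label"),
        dimension_vector=parse_dimension_vector(dim_text) if dim_text else None,
        si_multiplier=multiplier,
        si_offset=offset,
        ucum_codes=tuple(s for s in cell("ucum").split(";") if s.strip()),
        quantity_kinds=tuple(s for s in cell("quantity_kinds").split(";") if s.strip()),
        description=cell("description") or None,
    )
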