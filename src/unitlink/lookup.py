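"""The enriched lookup table: any supported key to a QUDT unit.

The table is the pipeline's reusable product.  It maps four kinds of key —
raw unit strings seen in a corpus, pseudounits, QUDT codes themselves, and
UCUM aliases longer than two characters (shorter codes are too ambiguous) —
to a QUDT unit, enriched with label, URI, dimension vector and SI
conversion parameters.  Distinct raw forms keep their own rows and use
counts; unmatched distinct units go to a sidecar candidate list ordered by
use count.

Value conversion is gated on exact dimension-vector equality: a unit only
converts to another with the identical vector (so milligrams per litre can
never silently convert to millimoles per litre — that needs the substance's
molar mass, which belongs to the measurement, not the unit).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .pseudo import to_pseudounit
from .rewrite import CandidateCode, MatchResult, map_pseudounit
from .rules import RuleSet
from .vocab import QudtUnit, UnitVocabulary

__all__ = [
    "LookupRecord",
    "LookupTable",
    "LookupError",
    "ConversionError",
    "build_lookup_table",
    "match_raw",
    "resolve",
    "compatible",
    "convert_value",
    "write_table",
    "read_table",
    "Resolver",
]

KEY_KINDS = ("raw", "pseudounit", "qudt_code", "ucum")

#: UCUM aliases of this length or shorter are excluded from the table
#: (single letters and digraphs collide across unit systems).
MAX_EXCLUDED_UCUM_LEN = 2


class LookupError(ValueError):
    """Raised for table build conflicts and malformed table files."""


class ConversionError(ValueError):
    """Raised when a conversion is dimensionally or parametrically impossible."""


@dataclass(frozen=True)
class LookupRecord:
    key: str
    key_kind: str
    qudt_code: str
    uri: str
    label: str
    dimension_vector: str = ""
    si_multiplier: float | None = None
    si_offset: float = 0.0
    ucum: str = ""
    description: str = ""
    n_uses: int = 0

    def __post_init__(self) -> None:
        if self.key_kind not in KEY_KINDS:
            raise LookupError(f"unknown key_kind {self.key_kind!r}")
        if self.n_uses < 0:
            raise LookupError("n_uses must be nonnegative")


class LookupTable:
    """Lookup records indexed by (key, key_kind), plus build metadata."""

    def __init__(
        self,
        records: Iterable[LookupRecord],
        vocabulary_version: str = "",
        rules_provenance: str = "",
        build_timestamp: str | None = None,
        unmatched: Sequence[tuple[str, int]] = (),
    ) -> None:
        self._index: dict[tuple[str, str], LookupRecord] = {}
        for rec in records:
            key = (rec.key, rec.key_kind)
            if key in self._index and self._index[key].qudt_code != rec.qudt_code:
                raise LookupError(
                    f"conflicting records for key {rec.key!r} ({rec.key_kind}): "
                    f"{self._index[key].qudt_code} vs {rec.qudt_code}"
                )
            self._index[key] = rec
        self.vocabulary_version = vocabulary_version
        self.rules_provenance = rules_provenance
        #: set at build time; deliberately not serialized, so a rebuild from
        #: identical inputs writes byte-identical output.
        self.build_timestamp = build_timestamp
        #: distinct raw forms that did not map, with use counts, ordered by
        #: use count descending — the candidate-units-for-QUDT list.
        self.unmatched: tuple[tuple[str, int], ...] = tuple(unmatched)

    @property
    def records(self) -> tuple[LookupRecord, ...]:
        return tuple(
            sorted(
                self._index.values(),
                key=lambda r: (KEY_KINDS.index(r.key_kind), r.key),
            )
        )

    def get(self, key: str, key_kind: str) -> LookupRecord | None:
        return self._index.get((key, key_kind))

    def __len__(self) -> int:
        return len(self._index)

    def kind_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(KEY_KINDS, 0)
        for rec in self._index.values():
            counts[rec.key_kind] += 1
        return counts


def _record_for(
    key: str, key_kind: str, unit: QudtUnit, n_uses: int = 0
) -> LookupRecord:
    return LookupRecord(
        key=key,
        key_kind=key_kind,
        qudt_code=unit.code,
        uri=unit.uri,
        label=unit.label,
        dimension_vector=unit.dimension_vector.render() if unit.dimension_vector else "",
        si_multiplier=unit.si_multiplier,
        si_offset=unit.si_offset,
        ucum=";".join(unit.ucum_codes),
        description=unit.description or "",
        n_uses=n_uses,
    )


def match_raw(
    raw: str,
    vocab: UnitVocabulary,
    pseudo_rules: RuleSet,
    qudt_rules: RuleSet,
) -> MatchResult:
    """Match one raw string directly against the vocabulary.

    Path order: exact QUDT code, exact UCUM alias (case-sensitive; a unique
    alias is required), then the pseudounit/rewrite pipeline.
    """
    query = raw.strip()
    unit = vocab.get(query)
    if unit is not None:
        return MatchResult(
            query=raw, pseudounit="", matched_unit=unit, match_path="direct_qudt_code"
        )
    codes = vocab.ucum_index.get(query, [])
    if len(codes) == 1:
        return MatchResult(
            query=raw, pseudounit="", matched_unit=vocab[codes[0]], match_path="ucum"
        )
    pseudo = to_pseudounit(raw, pseudo_rules)
    result = map_pseudounit(pseudo, qudt_rules, vocab)
    return replace(result, query=raw)


def build_lookup_table(
    corpus: Iterable[tuple[str, str, int]],
    vocab: UnitVocabulary,
    pseudo_rules: RuleSet,
    qudt_rules: RuleSet,
) -> LookupTable:
    """Build the enriched table from a corpus of (raw, organization, n_uses).

    The table contains one row per successfully mapped distinct raw form
    (with its summed use count), one row per vocabulary unit keyed by its
    own code, one row per successfully mapped pseudounit of the corpus, and
    one row per UCUM alias longer than two characters.  Conflicting
    enrichment (same key and kind, different code) is a build error.
    """
    uses_by_raw: dict[str, int] = {}
    for raw, _org, n_uses in corpus:
        key = raw.strip()
        uses_by_raw[key] = uses_by_raw.get(key, 0) + n_uses

    records: list[LookupRecord] = []
    conflicts: list[str] = []
    seen: dict[tuple[str, str], str] = {}

    def add(key: str, kind: str, unit: QudtUnit, n_uses: int = 0) -> None:
        prev = seen.get((key, kind))
        if prev is not None:
            if prev != unit.code:
                conflicts.append(f"{kind} key {key!r}: {prev} vs {unit.code}")
            return
        seen[(key, kind)] = unit.code
        records.append(_record_for(key, kind, unit, n_uses))

    unmatched: list[tuple[str, int]] = []
    pseudo_uses: dict[str, int] = {}
    pseudo_unit: dict[str, QudtUnit] = {}
    for raw in sorted(uses_by_raw):
        result = match_raw(raw, vocab, pseudo_rules, qudt_rules)
        if result.matched:
            add(raw, "raw", result.matched_unit, uses_by_raw[raw])
            pseudo = to_pseudounit(raw, pseudo_rules)
            mapped = map_pseudounit(pseudo, qudt_rules, vocab)
            if pseudo and mapped.matched:
                pseudo_uses[pseudo] = pseudo_uses.get(pseudo, 0) + uses_by_raw[raw]
                pseudo_unit[pseudo] = mapped.matched_unit
        else:
            unmatched.append((raw, uses_by_raw[raw]))

    for pseudo in sorted(pseudo_unit):
        add(pseudo, "pseudounit", pseudo_unit[pseudo], pseudo_uses[pseudo])

    for unit in sorted(vocab, key=lambda u: u.code):
        add(unit.code, "qudt_code", unit)
        for alias in unit.ucum_codes:
            if len(alias) > MAX_EXCLUDED_UCUM_LEN:
                add(alias, "ucum", unit)

    if conflicts:
        raise LookupError("lookup-table build conflicts: " + "; ".join(conflicts))

    unmatched.sort(key=lambda item: (-item[1], item[0]))
    from datetime import datetime, timezone

    return LookupTable(
        records,
        vocabulary_version=vocab.version,
        rules_provenance=f"{pseudo_rules.provenance};{qudt_rules.provenance}",
        build_timestamp=datetime.now(timezone.utc).isoformat(),
        unmatched=unmatched,
    )


def resolve(
    query: str,
    table: LookupTable,
    vocab: UnitVocabulary,
    pseudo_rules: RuleSet,
    qudt_rules: RuleSet,
) -> MatchResult:
    """Resolve a user-supplied unit string through the lookup table.

    Lookup order (first hit wins, recorded in ``match_path``): exact raw key
    after whitespace trimming (case-sensitive — ``mg`` vs ``MG`` style
    overloading makes case folding unsafe at this layer), exact QUDT code,
    exact UCUM alias, the query's pseudounit as a pseudounit key, and
    finally the full rewrite pipeline.
    """
    trimmed = query.strip()
    rec = table.get(trimmed, "raw")
    if rec is not None:
        return MatchResult(
            query=query, matched_unit=vocab[rec.qudt_code], match_path="direct_raw"
        )
    rec = table.get(trimmed, "qudt_code")
    if rec is not None:
        return MatchResult(
            query=query,
            matched_unit=vocab[rec.qudt_code],
            match_path="direct_qudt_code",
        )
    rec = table.get(trimmed, "ucum")
    if rec is not None:
        return MatchResult(
            query=query, matched_unit=vocab[rec.qudt_code], match_path="ucum"
        )
    pseudo = to_pseudounit(query, pseudo_rules)
    rec = table.get(pseudo, "pseudounit") if pseudo else None
    if rec is not None:
        return MatchResult(
            query=query,
            pseudounit=pseudo,
            matched_unit=vocab[rec.qudt_code],
            match_path="rewritten",
        )
    result = map_pseudounit(pseudo, qudt_rules, vocab)
    return replace(result, query=query)


def compatible(a: QudtUnit, b: QudtUnit) -> bool:
    """True iff the two units' dimension vectors are exactly equal."""
    if a.dimension_vector is None or b.dimension_vector is None:
        missing = a.code if a.dimension_vector is None else b.code
        raise ConversionError(f"unit {missing} has no published dimension vector")
    return a.dimension_vector == b.dimension_vector


def convert_value(x: float, from_unit: QudtUnit, to_unit: QudtUnit) -> float:
    """Convert a value between two dimensionally compatible units.

    ``y = (m_from * x + b_from - b_to) / m_to`` where ``m``/``b`` are each
    unit's SI multiplier and offset.  Round-trips to within float tolerance.
    """
    if not compatible(from_unit, to_unit):
        raise ConversionError(
            f"incompatible dimensions: {from_unit.code} "
            f"({from_unit.dimension_vector}) vs {to_unit.code} "
            f"({to_unit.dimension_vector})"
        )
    if from_unit.si_multiplier is None or to_unit.si_multiplier is None:
        missing = from_unit.code if from_unit.si_multiplier is None else to_unit.code
        raise ConversionError(f"unit {missing} has no published SI multiplier")
    return (from_unit.si_multiplier * x + from_unit.si_offset - to_unit.si_offset) / to_unit.si_multiplier


_COLUMNS = (
    "key",
    "key_kind",
    "qudt_code",
    "uri",
    "label",
    "dimension_vector",
    "si_multiplier",
    "si_offset",
    "ucum",
    "description",
    "n_uses",
)


def write_table(table: LookupTable, path: str | Path) -> None:
    """Serialize a table as UTF-8 delimited text.

    Output is a pure function of the table contents (records are sorted,
    floats written with ``repr``), so rebuilding from identical inputs
    yields byte-identical files.
    """
    import csv

    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# lookup table; vocabulary version: {table.vocabulary_version}\n")
        fh.write(f"# rules: {table.rules_provenance}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_COLUMNS)
        for rec in table.records:
            writer.writerow(
                [
                    rec.key,
                    rec.key_kind,
                    rec.qudt_code,
                    rec.uri,
                    rec.label,
                    rec.dimension_vector,
                    "" if rec.si_multiplier is None else repr(rec.si_multiplier),
                    repr(rec.si_offset),
                    rec.ucum,
                    rec.description,
                    rec.n_uses,
                ]
            )


def write_unmatched(table: LookupTable, path: str | Path) -> None:
    """Write the sidecar candidate-units list (unmatched raw forms)."""
    import csv

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["raw", "n_uses"])
        for raw, n_uses in table.unmatched:
            writer.writerow([raw, n_uses])


def read_table(path: str | Path) -> LookupTable:
    """Read a serialized lookup table."""
    import csv
    import io

    path = Path(path)
    if not path.is_file():
        raise LookupError(f"lookup table file not found: {path}")
    version = ""
    provenance = ""
    lines = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("lookup table; vocabulary version:"):
                version = body.split(":", 1)[1].strip()
            elif body.lower().startswith("rules:"):
                provenance = body.split(":", 1)[1].strip()
            continue
        lines.append(line)
    reader = csv.DictReader(io.StringIO("\n".join(lines)))
    missing = [c for c in _COLUMNS if c not in (reader.fieldnames or ())]
    if missing:
        raise LookupError(f"lookup table missing columns: {missing}")
    records = []
    for row in reader:
        records.append(
            LookupRecord(
                key=row["key"],
                key_kind=row["key_kind"],
                qudt_code=row["qudt_code"],
                uri=row["uri"],
                label=row["label"],
                dimension_vector=row["dimension_vector"] or "",
                si_multiplier=float(row["si_multiplier"]) if row["si_multiplier"] else None,
                si_offset=float(row["si_offset"]) if row["si_offset"] else 0.0,
                ucum=row["ucum"] or "",
                description=row["description"] or "",
                n_uses=int(row["n_uses"] or 0),
            )
        )
    return LookupTable(records, vocabulary_version=version, rules_provenance=provenance)


class Resolver:
    """Convenience bundle of table, vocabulary and rule sets.

    Builds the table from the given corpus (empty by default) and exposes a
    one-argument :meth:`resolve`, which is what the EML annotator, the web
    service and the corpus statistics all consume.
    """

    def __init__(
        self,
        vocab: UnitVocabulary,
        pseudo_rules: RuleSet,
        qudt_rules: RuleSet,
        table: LookupTable | None = None,
        corpus: Iterable[tuple[str, str, int]] = (),
    ) -> None:
        self.vocab = vocab
        self.pseudo_rules = pseudo_rules
        self.qudt_rules = qudt_rules
        self.table = table if table is not None else build_lookup_table(
            corpus, vocab, pseudo_rules, qudt_rules
        )

    @classmethod
    def default(cls) -> "Resolver":
        from .resources import default_pseudo_rules, default_qudt_rules, default_vocabulary

        return cls(default_vocabulary(), default_pseudo_rules(), default_qudt_rules())

    def resolve(self, query: str) -> MatchResult:
        return resolve(query, self.table, self.vocab, self.pseudo_rules, self.qudt_rules)
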