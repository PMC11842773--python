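"""Lookup-table build, resolution order, conversion, serialization."""

import itertools

import pytest

from unitlink.lookup import (
    ConversionError,
    LookupError,
    Resolver,
    build_lookup_table,
    compatible,
    convert_value,
    match_raw,
    read_table,
    resolve,
    write_table,
)
from unitlink.vocab import QudtUnit, UnitVocabulary, parse_dimension_vector


def n_long_ucum(vocab):
    return sum(
        1 for u in vocab for alias in u.ucum_codes if len(alias) > 2
    )


def test_build_counts_from_small_corpus(vocab, pseudo_rules, qudt_rules):
    table = build_lookup_table([("g/m2", "EDI", 5)], vocab, pseudo_rules, qudt_rules)
    counts = table.kind_counts()
    assert counts["raw"] == 1
    assert counts["pseudounit"] == 1
    assert counts["qudt_code"] == len(vocab)
    assert counts["ucum"] == n_long_ucum(vocab)
    raw_row = table.get("g/m2", "raw")
    assert raw_row.qudt_code == "GM-PER-M2"
    assert raw_row.n_uses == 5
    assert raw_row.label == "gram per square metre"
    assert raw_row.dimension_vector == "A0E0L-2I0M1H0T0D0"
    pseudo_row = table.get("grampermetersquared", "pseudounit")
    assert pseudo_row.qudt_code == "GM-PER-M2"


def test_build_empty_corpus(vocab, pseudo_rules, qudt_rules):
    table = build_lookup_table([], vocab, pseudo_rules, qudt_rules)
    counts = table.kind_counts()
    assert counts["raw"] == counts["pseudounit"] == 0
    assert counts["qudt_code"] == len(vocab)
    assert counts["ucum"] == n_long_ucum(vocab)
    assert table.unmatched == ()


def test_short_ucum_aliases_are_excluded(vocab, pseudo_rules, qudt_rules):
    table = build_lookup_table([], vocab, pseudo_rules, qudt_rules)
    assert table.get("m", "ucum") is None  # too short, too ambiguous
    assert table.get("kPa", "ucum").qudt_code == "KiloPA"


def test_junk_corpus_goes_to_unmatched_sidecar(vocab, pseudo_rules, qudt_rules):
    corpus = [("martha stewart", "EDI", 2), ("-9999", "NEON", 7), ("4a", "EDI", 1)]
    table = build_lookup_table(corpus, vocab, pseudo_rules, qudt_rules)
    assert table.kind_counts()["raw"] == 0
    # ordered by use count descending
    assert table.unmatched == (("-9999", 7), ("martha stewart", 2), ("4a", 1))


def test_raw_rows_keep_per_form_use_counts(vocab, pseudo_rules, qudt_rules):
    corpus = [("g/m2", "EDI", 5), ("g m-2", "NEON", 2), ("g/m2", "NEON", 4)]
    table = build_lookup_table(corpus, vocab, pseudo_rules, qudt_rules)
    assert table.get("g/m2", "raw").n_uses == 9
    assert table.get("g m-2", "raw").n_uses == 2
    # the shared pseudounit row pools the uses of its raw forms
    assert table.get("grampermetersquared", "pseudounit").n_uses == 11


def test_conflicting_ucum_enrichment_is_build_error(pseudo_rules, qudt_rules):
    units = [
        QudtUnit(code="AAA", uri="http://q/AAA", label="a",
                 dimension_vector=parse_dimension_vector("A0E0L0I0M0H0T0D1"),
                 si_multiplier=1.0, ucum_codes=("xxx",)),
        QudtUnit(code="BBB", uri="http://q/BBB", label="b",
                 dimension_vector=parse_dimension_vector("A0E0L0I0M0H0T0D1"),
                 si_multiplier=1.0, ucum_codes=("xxx",)),
    ]
    with pytest.raises(LookupError, match="conflict"):
        build_lookup_table([], UnitVocabulary(units), pseudo_rules, qudt_rules)


@pytest.mark.parametrize(
    "query, path, code",
    [
        ("gramPerMeterSquared", "rewritten", "GM-PER-M2"),
        ("GM-PER-M2", "direct_qudt_code", "GM-PER-M2"),
        ("kPa", "ucum", "KiloPA"),
        ("g/m2", "direct_raw", "GM-PER-M2"),
        ("  g/m2  ", "direct_raw", "GM-PER-M2"),  # trimmed
    ],
)
def test_resolve_path_order(query, path, code, vocab, pseudo_rules, qudt_rules):
    table = build_lookup_table([("g/m2", "EDI", 5)], vocab, pseudo_rules, qudt_rules)
    result = resolve(query, table, vocab, pseudo_rules, qudt_rules)
    assert result.match_path == path
    assert result.matched_unit.code == code


def test_resolve_unmatched_is_a_value(resolver):
    result = resolver.resolve("martha stewart")
    assert not result.matched
    assert result.match_path == "unmatched"


def test_internal_consistency_sweep(vocab, pseudo_rules, qudt_rules):
    """Every key already in the table resolves to the table's own code."""
    corpus = [("g/m2", "EDI", 5), ("degrees Celsius", "NEON", 3), ("m/s", "EDI", 8)]
    table = build_lookup_table(corpus, vocab, pseudo_rules, qudt_rules)
    for rec in table.records:
        result = resolve(rec.key, table, vocab, pseudo_rules, qudt_rules)
        assert result.matched, rec.key
        assert result.matched_unit.code == rec.qudt_code, rec.key


def test_match_raw_direct_code_and_ucum_paths(vocab, pseudo_rules, qudt_rules):
    assert match_raw("GM-PER-M2", vocab, pseudo_rules, qudt_rules).match_path == "direct_qudt_code"
    assert match_raw("cm", vocab, pseudo_rules, qudt_rules).match_path == "ucum"


def test_compatible(vocab):
    assert compatible(vocab["GM-PER-M2"], vocab["KiloGM-PER-HA"])
    assert not compatible(vocab["MilliGM-PER-L"], vocab["MilliMOL-PER-L"])
    assert compatible(vocab["M"], vocab["M"])


def test_compatible_missing_vector_is_error(vocab):
    bare = QudtUnit(code="X", uri="http://q/X", label="x", si_multiplier=1.0)
    with pytest.raises(ConversionError, match="dimension vector"):
        compatible(bare, vocab["M"])


@pytest.mark.parametrize(
    "x, src, dst, expected",
    [
        (1.0, "M", "CentiM", 100.0),
        (0.0, "DEG_C", "K", 273.15),
        (1.0, "GM-PER-M2", "KiloGM-PER-HA", 10.0),
        (32.0, "DEG_F", "DEG_C", 0.0),
        (1.0, "MilliMOL-PER-L", "MicroMOL-PER-L", 1000.0),
    ],
)
def test_convert_value_closed_forms(vocab, x, src, dst, expected):
    assert convert_value(x, vocab[src], vocab[dst]) == pytest.approx(expected, rel=1e-12, abs=1e-9)


def test_convert_incompatible_refused(vocab):
    with pytest.raises(ConversionError, match="incompatible"):
        convert_value(1.0, vocab["MilliGM-PER-L"], vocab["MilliMOL-PER-L"])


def test_convert_roundtrip_over_all_compatible_pairs(vocab):
    units = list(vocab)
    for a, b in itertools.combinations(units, 2):
        if a.dimension_vector != b.dimension_vector:
            continue
        for x in (0.0, 1.0, -3.5, 12345.678):
            y = convert_value(x, a, b)
            back = convert_value(y, b, a)
            assert back == pytest.approx(x, rel=1e-9, abs=1e-9), (a.code, b.code)


def test_serialized_table_is_byte_identical_across_rebuilds(tmp_path, vocab, pseudo_rules, qudt_rules):
    corpus = [("g/m2", "EDI", 5), ("celsius", "NEON", 2)]
    paths = []
    for name in ("a.csv", "b.csv"):
        table = build_lookup_table(corpus, vocab, pseudo_rules, qudt_rules)
        path = tmp_path / name
        write_table(table, path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_table_read_write_roundtrip(tmp_path, vocab, pseudo_rules, qudt_rules):
    table = build_lookup_table([("g/m2", "EDI", 5)], vocab, pseudo_rules, qudt_rules)
    path = tmp_path / "table.csv"
    write_table(table, path)
    loaded = read_table(path)
    assert len(loaded) == len(table)
    assert loaded.vocabulary_version == vocab.version
    rec = loaded.get("g/m2", "raw")
    assert rec.qudt_code == "GM-PER-M2" and rec.n_uses == 5
    # a resolver over the deserialized table behaves identically
    r = Resolver(vocab, pseudo_rules, qudt_rules, table=loaded)
    assert r.resolve("g/m2").match_path == "direct_raw"
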