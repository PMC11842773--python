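"""Corpus tabulations and the synthetic corpus generator."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unitlink.corpus import (
    JUNK,
    SyntheticSpec,
    UnitCorpus,
    generate_synthetic_corpus,
    match_summary,
    read_corpus,
    tabulate_corpus,
    write_corpus,
)
from unitlink.lookup import match_raw


def test_tabulate_small_corpus():
    stats = tabulate_corpus(UnitCorpus([("m", "A", 3), ("m", "B", 2), ("x", "A", 1)]))
    assert stats.n_distinct == 2
    assert stats.total_instances == 6
    assert stats.overlap == {1: (1, 1), 2: (1, 5)}
    assert stats.histogram == {1: (1, 1), 5: (1, 5)}


def test_tabulate_empty_corpus():
    stats = tabulate_corpus(UnitCorpus([]))
    assert stats.n_distinct == 0 and stats.total_instances == 0
    assert stats.histogram == {} and stats.overlap == {}


def test_tabulate_all_singletons():
    corpus = UnitCorpus([(f"u{i}", "A", 1) for i in range(7)])
    stats = tabulate_corpus(corpus)
    assert stats.histogram == {1: (7, 7)}


corpora = st.lists(
    st.tuples(
        st.sampled_from(["m", "g/m2", "x", "y", "z"]),
        st.sampled_from(["A", "B", "C"]),
        st.integers(min_value=1, max_value=50),
    ),
    max_size=30,
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(corpora)
def test_tabulate_conservation_identities(entries):
    stats = tabulate_corpus(UnitCorpus(entries))
    assert sum(d for d, _ in stats.overlap.values()) == stats.n_distinct
    assert sum(i for _, i in stats.overlap.values()) == stats.total_instances
    assert sum(d for d, _ in stats.histogram.values()) == stats.n_distinct
    assert sum(i for _, i in stats.histogram.values()) == stats.total_instances


def test_match_summary_skew_arithmetic(vocab, pseudo_rules, qudt_rules):
    """10% of distinct units mappable but 91% of instances mappable."""
    mappable = ["m", "g/m2", "celsius", "m/s", "percent", "kPa", "mg/L", "mol", "day", "ha"]
    entries = [(raw, "EDI", 91) for raw in mappable]
    entries += [(f"junk token {i}", "EDI", 1) for i in range(90)]
    stats = match_summary(UnitCorpus(entries), vocab, pseudo_rules, qudt_rules)
    assert stats.n_distinct == 100
    assert stats.n_distinct_matched == 10
    assert stats.distinct_match_percent == 10.0
    assert stats.instance_match_percent == 91.0


def test_match_summary_all_junk(vocab, pseudo_rules, qudt_rules):
    stats = match_summary(
        UnitCorpus([("-9999", "A", 1), ("atlantis", "B", 2)]),
        vocab, pseudo_rules, qudt_rules,
    )
    assert stats.n_distinct_matched == 0
    assert stats.instance_match_percent == 0.0


@pytest.fixture(scope="module")
def synthetic(vocab, pseudo_rules, qudt_rules):
    spec = SyntheticSpec(seed=1, n_distinct=200, zipf_exponent=1.5, junk_fraction=0.10)
    return generate_synthetic_corpus(spec, vocab, pseudo_rules, qudt_rules)


def test_generator_is_deterministic(vocab, pseudo_rules, qudt_rules, synthetic):
    spec = SyntheticSpec(seed=1, n_distinct=200, zipf_exponent=1.5, junk_fraction=0.10)
    corpus2, truth2 = generate_synthetic_corpus(spec, vocab, pseudo_rules, qudt_rules)
    corpus1, truth1 = synthetic
    assert corpus1.as_tuples() == corpus2.as_tuples()
    assert truth1 == truth2


def test_generator_without_junk(vocab, pseudo_rules, qudt_rules):
    spec = SyntheticSpec(seed=1, n_distinct=50, junk_fraction=0.0)
    _, truth = generate_synthetic_corpus(spec, vocab, pseudo_rules, qudt_rules)
    assert len(truth) == 50
    assert all(code != JUNK for code in truth.values())


def test_zipf_use_counts_concentrate_instances(synthetic):
    corpus, _ = synthetic
    stats = tabulate_corpus(corpus)
    top10 = sum(sorted(stats.use_counts.values(), reverse=True)[:10])
    assert top10 / stats.total_instances >= 0.5


def test_recovery_and_skew_on_synthetic_corpus(vocab, pseudo_rules, qudt_rules, synthetic):
    corpus, truth = synthetic
    stats = match_summary(corpus, vocab, pseudo_rules, qudt_rules)
    # junk is 10% of distinct forms, all singletons: instances overwhelmingly match
    assert stats.instance_match_percent >= 90.0
    assert stats.distinct_match_percent <= stats.instance_match_percent
    # zero wrong codes: every matched form maps to its ground truth, junk never matches
    for raw, code in truth.items():
        result = match_raw(raw, vocab, pseudo_rules, qudt_rules)
        if code == JUNK:
            assert not result.matched, raw
        else:
            assert result.matched, raw
            assert result.matched_unit.code == code, raw


def test_truth_and_corpus_cover_same_forms(synthetic):
    corpus, truth = synthetic
    assert {e.raw for e in corpus.entries} == set(truth)
    assert len(truth) == 200


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_distinct=0),
        dict(junk_fraction=1.5),
        dict(zipf_exponent=1.0),
        dict(max_variants_per_unit=0),
        dict(org_weights={}),
    ],
)
def test_invalid_spec_rejected(kwargs):
    with pytest.raises(ValueError):
        SyntheticSpec(**kwargs)


def test_corpus_file_roundtrip(tmp_path, synthetic):
    corpus, truth = synthetic
    path = tmp_path / "corpus.csv"
    write_corpus(corpus, path, truth=truth, truth_path=tmp_path / "truth.csv")
    loaded = read_corpus(path)
    assert loaded.as_tuples() == corpus.as_tuples()
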