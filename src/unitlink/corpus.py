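"""Corpus statistics and a synthetic raw-unit corpus generator.

Real unit-string corpora harvested from metadata repositories are heavily
skewed: most distinct unit strings occur exactly once (and many of those
are not units at all — site names, missing-value codes, dates), while a
handful of conventional forms account for the bulk of all uses.  The
statistics here tabulate that structure — distinct counts, the use-count
histogram, the organization-overlap partition, and match rates against the
vocabulary — and the generator emulates it so the whole pipeline is
testable without downloading any corpus: Zipf-distributed use counts,
several surface variants per underlying unit (symbolic, spelled-out,
camelCase, negative-exponent, misspelled), and a junk fraction of
guaranteed-unresolvable non-unit strings concentrated in singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lookup import match_raw
from .rules import RuleSet
from .vocab import UnitVocabulary

__all__ = [
    "JUNK",
    "CorpusEntry",
    "UnitCorpus",
    "CorpusStats",
    "SyntheticSpec",
    "tabulate_corpus",
    "match_summary",
    "generate_synthetic_corpus",
    "write_corpus",
    "read_corpus",
]

#: Ground-truth marker for generated non-unit strings.
JUNK = "JUNK"


@dataclass(frozen=True)
class CorpusEntry:
    raw: str
    org: str
    n_uses: int

    def __post_init__(self) -> None:
        if self.n_uses < 1:
            raise ValueError(f"n_uses must be >= 1, got {self.n_uses}")


class UnitCorpus:
    """Raw-unit instances with organization labels."""

    def __init__(self, entries: Iterable[CorpusEntry | tuple[str, str, int]]) -> None:
        self.entries: tuple[CorpusEntry, ...] = tuple(
            e if isinstance(e, CorpusEntry) else CorpusEntry(*e) for e in entries
        )

    @property
    def organizations(self) -> frozenset[str]:
        return frozenset(e.org for e in self.entries)

    @property
    def total_instances(self) -> int:
        return sum(e.n_uses for e in self.entries)

    def as_tuples(self) -> list[tuple[str, str, int]]:
        return [(e.raw, e.org, e.n_uses) for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CorpusStats:
    """Tabulations over a corpus; match summary fields are optional."""

    total_instances: int
    n_distinct: int
    use_counts: dict[str, int]
    #: use-count value -> (number of distinct units with that count,
    #: number of instances they contribute) — the two axes of the skew plot.
    histogram: dict[int, tuple[int, int]]
    #: number of organizations k -> (distinct units used by exactly k
    #: organizations, instances they contribute).
    overlap: dict[int, tuple[int, int]]
    n_distinct_matched: int | None = None
    n_instances_matched: int | None = None
    distinct_match_percent: float | None = None
    instance_match_percent: float | None = None


def tabulate_corpus(corpus: UnitCorpus) -> CorpusStats:
    """Distinct counts, use-count histogram and organization overlap.

    Distinct counting is exact-string (no normalization here).  Conservation
    identities hold by construction: histogram and overlap each partition
    both the distinct units and the instances.
    """
    uses: dict[str, int] = {}
    orgs: dict[str, set[str]] = {}
    for e in corpus.entries:
        uses[e.raw] = uses.get(e.raw, 0) + e.n_uses
        orgs.setdefault(e.raw, set()).add(e.org)
    histogram: dict[int, tuple[int, int]] = {}
    for raw, n in uses.items():
        d, i = histogram.get(n, (0, 0))
        histogram[n] = (d + 1, i + n)
    overlap: dict[int, tuple[int, int]] = {}
    for raw, n in uses.items():
        k = len(orgs[raw])
        d, i = overlap.get(k, (0, 0))
        overlap[k] = (d + 1, i + n)
    return CorpusStats(
        total_instances=sum(uses.values()),
        n_distinct=len(uses),
        use_counts=uses,
        histogram=dict(sorted(histogram.items())),
        overlap=dict(sorted(overlap.items())),
    )


def match_summary(
    corpus: UnitCorpus,
    vocab: UnitVocabulary,
    pseudo_rules: RuleSet,
    qudt_rules: RuleSet,
) -> CorpusStats:
    """Corpus tabulations plus match rates against the vocabulary.

    Percentages are reported to 0.1%.
    """
    stats = tabulate_corpus(corpus)
    matched_distinct = 0
    matched_instances = 0
    for raw, n in stats.use_counts.items():
        if match_raw(raw, vocab, pseudo_rules, qudt_rules).matched:
            matched_distinct += 1
            matched_instances += n
    stats.n_distinct_matched = matched_distinct
    stats.n_instances_matched = matched_instances
    stats.distinct_match_percent = (
        round(100.0 * matched_distinct / stats.n_distinct, 1) if stats.n_distinct else 0.0
    )
    stats.instance_match_percent = (
        round(100.0 * matched_instances / stats.total_instances, 1)
        if stats.total_instances
        else 0.0
    )
    return stats


# --------------------------------------------------------------------------
# synthetic corpus generation

#: token -> (symbol, word singular, word plural, negative-exponent form)
#: Only QUDT codes whose every token appears here are sampled, so every
#: generated variant is a form the default rules cover.
_TOKEN_FORMS: dict[str, tuple[str, str, str, str | None]] = {
    "GM": ("g", "gram", "grams", "g-1"),
    "KiloGM": ("kg", "kilogram", "kilograms", "kg-1"),
    "MilliGM": ("mg", "milligram", "milligrams", None),
    "MicroGM": ("ug", "microgram", "micrograms", None),
    "M": ("m", "meter", "meters", "m-1"),
    "CentiM": ("cm", "centimeter", "centimeters", None),
    "MilliM": ("mm", "millimeter", "millimeters", None),
    "KiloM": ("km", "kilometer", "kilometers", None),
    "MicroM": ("um", "micrometer", "micrometers", None),
    "NanoM": ("nm", "nanometer", "nanometers", None),
    "M2": ("m2", "square meter", "square meters", "m-2"),
    "CentiM2": ("cm2", "square centimeter", "square centimeters", "cm-2"),
    "KiloM2": ("km2", "square kilometer", "square kilometers", "km-2"),
    "M3": ("m3", "cubic meter", "cubic meters", "m-3"),
    "CentiM3": ("cm3", "cubic centimeter", "cubic centimeters", "cm-3"),
    "L": ("l", "liter", "liters", "l-1"),
    "MilliL": ("ml", "milliliter", "milliliters", None),
    "SEC": ("s", "second", "seconds", "s-1"),
    "MIN": ("min", "minute", "minutes", "min-1"),
    "HR": ("h", "hour", "hours", "h-1"),
    "DAY": ("d", "day", "days", "d-1"),
    "YR": ("yr", "year", "years", "yr-1"),
    "K": ("K", "kelvin", "kelvins", None),
    "DEG_C": ("°C", "degrees celsius", "degrees celsius", None),
    "DEG_F": ("°F", "degrees fahrenheit", "degrees fahrenheit", None),
    "HA": ("ha", "hectare", "hectares", "ha-1"),
    "MOL": ("mol", "mole", "moles", None),
    "MilliMOL": ("mmol", "millimole", "millimoles", None),
    "MicroMOL": ("umol", "micromole", "micromoles", None),
    "PA": ("Pa", "pascal", "pascals", None),
    "KiloPA": ("kPa", "kilopascal", "kilopascals", None),
    "HectoPA": ("hPa", "hectopascal", "hectopascals", None),
    "PERCENT": ("%", "percent", "percent", None),
    "PERMILLE": ("‰", "per mille", "per mille", None),
    "NUM": ("#", "number", "numbers", None),
    "UNITLESS": ("dimensionless", "dimensionless", "dimensionless", None),
    "J": ("J", "joule", "joules", None),
    "W": ("W", "watt", "watts", None),
    "HZ": ("Hz", "hertz", "hertz", None),
}

#: word -> misspelling the default rule set repairs.
_MISSPELLINGS = {
    "centimeter": "cenimeter",
    "celsius": "celcius",
    "fahrenheit": "farenheit",
}

_JUNK_BASE = [
    "-9999",
    "9999",
    "4a",
    "n/a",
    "none",
    "unknown",
    "martha stewart",
    "atlantis/alvin",
    "yyyy-mm-dd",
    "hh:mm:ss",
    "see methods",
    "detection limit",
    "category",
    "various",
    "blank",
    "station",
    "quadrat",
    "sample id",
    "pit tag",
]

_VARIANT_STYLES = (
    "symbolic",
    "symbolic_spaced",
    "spelled",
    "spelled_singular",
    "camel",
    "negexp",
    "misspelled",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus.

    ``n_distinct`` counts distinct raw forms including junk;
    ``zipf_exponent`` shapes the use-count distribution of true unit forms
    (junk strings are singletons); ``junk_fraction`` is the fraction of
    distinct forms that are non-units.  Identical seeds give identical
    corpora.
    """

    seed: int = 0
    n_distinct: int = 200
    max_variants_per_unit: int = 5
    zipf_exponent: float = 1.5
    junk_fraction: float = 0.10
    org_weights: Mapping[str, float] = field(
        default_factory=lambda: {"EDI": 0.50, "DataONE": 0.45, "NEON": 0.05}
    )

    def __post_init__(self) -> None:
        if self.n_distinct < 1:
            raise ValueError("n_distinct must be >= 1")
        if not 0.0 <= self.junk_fraction <= 1.0:
            raise ValueError("junk_fraction must be in [0, 1]")
        if self.zipf_exponent <= 1.0:
            raise ValueError("zipf_exponent must be > 1")
        if self.max_variants_per_unit < 1:
            raise ValueError("max_variants_per_unit must be >= 1")
        if not self.org_weights or any(w < 0 for w in self.org_weights.values()):
            raise ValueError("org_weights must be nonnegative and nonempty")


def _split_per(code: str) -> tuple[list[str], list[str]]:
    tokens = code.split("-")
    if "PER" in tokens:
        i = tokens.index("PER")
        return tokens[:i], tokens[i + 1 :]
    return tokens, []


def _render(code: str, style: str) -> str | None:
    numer, denom = _split_per(code)
    forms = _TOKEN_FORMS
    if any(t not in forms for t in numer + denom):
        return None
    sym = lambda t: forms[t][0]
    word = lambda t: forms[t][1]
    plural = lambda t: forms[t][2]

    if style in ("symbolic", "symbolic_spaced"):
        joiner = " / " if style == "symbolic_spaced" else "/"
        top = ".".join(sym(t) for t in numer)
        if denom:
            bottom = ".".join(sym(t) for t in denom)
            return (top + joiner + bottom) if top else "/" + bottom
        return top or None
    if style in ("spelled", "spelled_singular", "misspelled"):
        words = []
        for i, t in enumerate(numer):
            words.append(plural(t) if (style != "spelled_singular" and i == 0) else word(t))
        for t in denom:
            words.append("per " + word(t))
        text = " ".join(words).strip()
        if not text:
            text = " ".join("per " + word(t) for t in denom)
        if style == "misspelled":
            for good, bad in _MISSPELLINGS.items():
                if good in text:
                    return text.replace(good, bad)
            return None  # no applicable misspelling
        return text or None
    if style == "camel":
        words = []
        for t in numer:
            words.extend(word(t).split())
        for t in denom:
            words.append("per")
            words.extend(word(t).split())
        if not words:
            return None
        if any(not w.isalpha() for w in words):
            return None
        return words[0] + "".join(w.capitalize() for w in words[1:])
    if style == "negexp":
        if not denom or not numer:
            return None
        neg = [forms[t][3] for t in denom]
        if any(n is None for n in neg):
            return None
        return " ".join([sym(t) for t in numer] + neg)  # e.g. "g m-2 d-1"
    raise ValueError(f"unknown style {style!r}")


def _symbolic_fallback(code: str) -> str | None:
    numer, denom = _split_per(code)
    forms = _TOKEN_FORMS
    if any(t not in forms for t in numer + denom):
        return None
    top = ".".join(forms[t][0] for t in numer)
    if denom:
        return top + "/" + ".".join(forms[t][0] for t in denom)
    return top or None


def covered_codes(vocab: UnitVocabulary) -> list[str]:
    """Vocabulary codes the variant grammar can render."""
    out = []
    for unit in vocab:
        numer, denom = _split_per(unit.code)
        if all(t in _TOKEN_FORMS for t in numer + denom):
            out.append(unit.code)
    return sorted(out)


def generate_synthetic_corpus(
    spec: SyntheticSpec,
    vocab: UnitVocabulary,
    pseudo_rules: RuleSet,
    qudt_rules: RuleSet,
) -> tuple[UnitCorpus, dict[str, str]]:
    """Generate a corpus and its ground truth map (raw form -> code or JUNK).

    True units are drawn from the vocabulary subset the variant grammar
    covers; each is rendered in one of several surface styles.  Use counts
    of true forms are Zipf distributed so a small subset dominates instance
    counts; junk strings are singletons and are verified unresolvable at
    generation time.
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    rng = np.random.default_rng(spec.seed)
    codes = covered_codes(vocab)
    if not codes:
        raise ValueError("vocabulary has no codes the variant grammar covers")

    n_junk = int(round(spec.junk_fraction * spec.n_distinct))
    n_true = spec.n_distinct - n_junk

    truth: dict[str, str] = {}
    true_forms: list[str] = []
    attempts = 0
    while len(true_forms) < n_true:
        attempts += 1
        if attempts > 200 * spec.n_distinct:
            raise ValueError(
                f"variant grammar cannot produce {n_true} distinct forms from "
                f"{len(codes)} covered units"
            )
        code = codes[rng.integers(len(codes))]
        n_variants = int(rng.integers(1, spec.max_variants_per_unit + 1))
        styles = rng.choice(len(_VARIANT_STYLES), size=n_variants, replace=False)
        for si in styles:
            raw = _render(code, _VARIANT_STYLES[si]) or _symbolic_fallback(code)
            if raw is None or raw in truth:
                continue
            truth[raw] = code
            true_forms.append(raw)
            if len(true_forms) >= n_true:
                break

    junk_forms: list[str] = []
    i = 0
    pool = list(_JUNK_BASE)
    while len(junk_forms) < n_junk:
        if pool:
            cand = pool.pop(0)
        else:
            i += 1
            cand = f"site {i}" if i % 2 else f"code-{9000 + i}"
        if cand in truth:
            continue
        # construction check: junk must not resolve
        if match_raw(cand, vocab, pseudo_rules, qudt_rules).matched:
            continue
        truth[cand] = JUNK
        junk_forms.append(cand)

    org_names = sorted(spec.org_weights)
    weights = np.array([spec.org_weights[o] for o in org_names], dtype=float)
    weights = weights / weights.sum()

    entries: list[CorpusEntry] = []
    for raw in true_forms + junk_forms:
        if truth[raw] == JUNK:
            n_uses = 1
        else:
            n_uses = int(min(rng.zipf(spec.zipf_exponent), 50_000))
        # widely used units are used by several organizations
        if n_uses >= 100 and len(org_names) >= 3:
            k = 3
        elif n_uses >= 10 and len(org_names) >= 2:
            k = 2
        else:
            k = 1
        chosen = rng.choice(len(org_names), size=k, replace=False, p=weights)
        shares = np.ones(k, dtype=int)
        remaining = n_uses - k
        if remaining > 0:
            shares += rng.multinomial(remaining, np.ones(k) / k)
        for j, oi in enumerate(chosen):
            entries.append(CorpusEntry(raw, org_names[int(oi)], int(shares[j])))

    return UnitCorpus(entries), truth


def write_corpus(corpus: UnitCorpus, path, truth: Mapping[str, str] | None = None, truth_path=None) -> None:
    """Write a corpus (raw, org, n_uses) and optional ground truth sidecar."""
    import csv
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["raw", "org", "n_uses"])
        for e in corpus.entries:
            writer.writerow([e.raw, e.org, e.n_uses])
    if truth is not None and truth_path is not None:
        with Path(truth_path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["raw", "qudt_code"])
            for raw in sorted(truth):
                writer.writerow([raw, truth[raw]])


def read_corpus(path) -> UnitCorpus:
    import csv
    from pathlib import Path

    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        return UnitCorpus(
            (row["raw"], row["org"], int(row["n_uses"])) for row in reader
        )
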