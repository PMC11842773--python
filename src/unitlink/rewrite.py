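"""Pseudounits to QUDT unit codes via the second substitution phase.

Replacements in the qudt phase are dash-delimited, QUDT-cased tokens
(``-M2-``, ``-CentiM-``, ``-DEG_C-``).  Because pseudounits cannot contain
dashes, already-converted segments are visibly distinct from unconverted
text while the rules run.  Finalization then applies QUDT's code
conventions: no leading/trailing dash, no dash runs, and a single ``PER``
divider (numerator/denominator boundary); ``PER`` tokens beyond the first
collapse to plain dashes, so ``GM-PER-M2-PER-DAY`` becomes the published
code ``GM-PER-M2-DAY``.

Concept qualifiers joined by underscore (``DEG_C``, ``GAL_US``) are lexical
atoms: they are produced only as whole replacement tokens and the finalizer
never inserts or splits underscores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .rules import RuleSet
from .vocab import QudtUnit, UnitVocabulary

__all__ = [
    "CandidateCode",
    "MatchResult",
    "rewrite_to_candidate",
    "finalize_candidate",
    "map_pseudounit",
]


@dataclass(frozen=True)
class CandidateCode:
    """Result of the qudt-phase rewrite of one pseudounit.

    ``trace`` records ``(rule order, before, after)`` for every rule that
    changed the string, in application order.
    """

    marked: str
    finalized: str
    trace: tuple[tuple[int, str, str], ...] = ()


@dataclass(frozen=True)
class MatchResult:
    """Outcome of resolving one query string against the vocabulary."""

    query: str
    pseudounit: str = ""
    candidate: CandidateCode | None = None
    matched_unit: QudtUnit | None = None
    match_path: str = "unmatched"  # direct_raw | direct_qudt_code | ucum | rewritten | unmatched

    def __post_init__(self) -> None:
        if (self.matched_unit is not None) != (self.match_path != "unmatched"):
            raise ValueError(
                "matched_unit must be present exactly when match_path != unmatched"
            )

    @property
    def matched(self) -> bool:
        return self.match_path != "unmatched"


def rewrite_to_candidate(pseudounit: str, rules: RuleSet) -> CandidateCode:
    """Apply the qudt-phase rules strictly in order to one pseudounit.

    Each rule replaces all occurrences of its literal pattern.  Unknown text
    passes through untouched (the marked string then equals the input and
    finalization is a no-op), so an unmatched candidate is still useful as a
    diagnostic or as an entry on a candidate-units list.
    """
    if rules.phase != "qudt":
        raise ValueError(f"expected a qudt-phase rule set, got {rules.phase!r}")
    if "-" in pseudounit:
        raise ValueError(f"pseudounit {pseudounit!r} may not contain dashes")
    text = pseudounit
    trace: list[tuple[int, str, str]] = []
    for rule in rules:
        new = rule.apply(text)
        if new != text:
            trace.append((rule.order, text, new))
            text = new
    return CandidateCode(marked=text, finalized=finalize_candidate(text), trace=tuple(trace))


def finalize_candidate(marked: str) -> str:
    """Apply QUDT code-formatting conventions to a marked candidate.

    Strips leading/trailing dashes, collapses dash runs, and keeps only the
    first ``PER`` token — each subsequent ``-PER-`` collapses to a single
    dash.  Idempotent for all inputs.
    """
    text = re.sub(r"-{2,}", "-", marked.strip("-"))
    tokens = text.split("-")
    out: list[str] = []
    seen_per = False
    for tok in tokens:
        if tok == "PER":
            if seen_per:
                continue
            seen_per = True
        out.append(tok)
    return "-".join(t for t in out if t != "")


def map_pseudounit(
    pseudounit: str, rules: RuleSet, vocab: UnitVocabulary
) -> MatchResult:
    """Rewrite one pseudounit and look the finalized code up in the vocabulary.

    An unmatched result is a value, not an error: the candidate code is
    retained for diagnostics and candidate-unit lists.
    """
    candidate = rewrite_to_candidate(pseudounit, rules)
    unit = vocab.get(candidate.finalized)
    if unit is None:
        return MatchResult(
            query=pseudounit, pseudounit=pseudounit, candidate=candidate
        )
    return MatchResult(
        query=pseudounit,
        pseudounit=pseudounit,
        candidate=candidate,
        matched_unit=unit,
        match_path="rewritten",
    )
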