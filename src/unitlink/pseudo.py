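"""Raw unit strings to canonical "pseudounits".

A pseudounit is the lowercase, symbol-free canonical form that groups
surface variants of one underlying unit: ``gramPerMeterSquared``,
``grams per square meter``, ``g/m2`` and ``g m-2`` all become
``grampermetersquared``.  Processing is a pure function of the input and
the rule set:

1. Unicode compatibility decomposition (so micro signs coincide and
   superscript digits become plain digits), then lowercasing.
2. Whitespace runs collapsed to single spaces; one space padded on each
   end so rule patterns can use spaces as token anchors (a pattern
   ``" m2 "`` matches the token ``m2`` but not the tail of ``cm2``).
3. Each rule applied in order, replacing all occurrences; whitespace is
   re-collapsed after every rule so anchors stay stable.
4. Remaining whitespace deleted, then every character outside ``[a-z0-9]``
   deleted.

Any input yields a (possibly empty) pseudounit; an empty result means
nothing unit-like survived.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

from .rules import RuleSet

__all__ = ["Pseudounit", "to_pseudounit", "tabulate_pseudounits"]

_ALLOWED = re.compile(r"[^a-z0-9]")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class Pseudounit:
    """A pseudounit with the raw forms that normalized to it."""

    text: str
    source_raw_forms: tuple[str, ...] = ()
    n_uses: int = 0

    def __post_init__(self) -> None:
        if _ALLOWED.search(self.text):
            raise ValueError(
                f"pseudounit {self.text!r} contains characters outside [a-z0-9]"
            )
        if self.n_uses < 0:
            raise ValueError("n_uses must be nonnegative")


def to_pseudounit(raw: str, rules: RuleSet) -> str:
    """Normalize one raw unit string to its pseudounit text."""
    if rules.phase != "pseudo":
        raise ValueError(f"expected a pseudo-phase rule set, got {rules.phase!r}")
    text = unicodedata.normalize("NFKD", raw.strip()).lower()
    text = " " + _WS.sub(" ", text).strip() + " "
    for rule in rules:
        new = rule.apply(text)
        if new != text:
            text = " " + _WS.sub(" ", new).strip() + " "
    text = _WS.sub("", text)
    return _ALLOWED.sub("", text)


def tabulate_pseudounits(
    raws: list[tuple[str, int]], rules: RuleSet
) -> dict[str, tuple[int, int]]:
    """Group raw forms by pseudounit.

    Returns ``{pseudounit: (n_distinct_raw_forms, total_uses)}``.  The sum
    of ``total_uses`` over the map equals the sum of the input use counts.
    """
    forms: dict[str, set[str]] = {}
    uses: dict[str, int] = {}
    for raw, n_uses in raws:
        if n_uses < 1:
            raise ValueError(f"n_uses must be >= 1, got {n_uses} for {raw!r}")
        p = to_pseudounit(raw, rules)
        forms.setdefault(p, set()).add(raw)
        uses[p] = uses.get(p, 0) + n_uses
    return {p: (len(forms[p]), uses[p]) for p in forms}
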