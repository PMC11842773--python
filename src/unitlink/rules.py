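"""Ordered literal-substitution rule sets.

Both normalization phases — raw string to pseudounit, pseudounit to QUDT
candidate code — are driven by the same primitive: an ordered list of literal
substring substitutions.  Patterns are plain substrings, not a pattern
language; each rule replaces *all* occurrences of its pattern in one pass,
and rule order is the single source of control (earlier rules fire first
over the whole string).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = ["RewriteRule", "RuleSet", "RuleError", "load_rules"]


class RuleError(ValueError):
    """Raised for malformed rule files or invariant violations."""


@dataclass(frozen=True)
class RewriteRule:
    """One literal substring substitution.

    ``order`` is unique within a rule set and defines total application
    order.  For the pseudo phase the replacement may contain neither
    uppercase letters nor dashes (pseudounits must stay lowercase and
    dash-free so the QUDT phase can use dashes to mark converted segments).
    """

    order: int
    pattern: str
    replacement: str
    phase: str  # "pseudo" | "qudt"

    def __post_init__(self) -> None:
        if self.phase not in ("pseudo", "qudt"):
            raise RuleError(f"unknown phase {self.phase!r}")
        if not self.pattern:
            raise RuleError("rule pattern must be nonempty")
        if self.order <= 0:
            raise RuleError(f"rule order must be positive, got {self.order}")
        if self.phase == "pseudo":
            if any(c.isupper() for c in self.replacement) or "-" in self.replacement:
                raise RuleError(
                    f"pseudo-phase replacement {self.replacement!r} may not "
                    "contain uppercase letters or dashes"
                )

    def apply(self, text: str) -> str:
        return text.replace(self.pattern, self.replacement)


@dataclass(frozen=True)
class RuleSet:
    """An ordered rule list for one phase, with a provenance note."""

    phase: str
    rules: tuple[RewriteRule, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        orders = [r.order for r in self.rules]
        if len(set(orders)) != len(orders):
            dupes = sorted({o for o in orders if orders.count(o) > 1})
            raise RuleError(f"duplicate rule order values: {dupes}")
        if any(r.phase != self.phase for r in self.rules):
            raise RuleError("all rules in a set must share the set's phase")
        object.__setattr__(
            self, "rules", tuple(sorted(self.rules, key=lambda r: r.order))
        )

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def load_rules(path: str | Path, phase: str) -> RuleSet:
    """Load a rule set from a delimited text file.

    The file has a header row with columns ``order, pattern, replacement``;
    lines whose first non-blank character is ``#`` are comments.  Patterns
    and replacements are taken literally (quote cells to preserve leading or
    trailing spaces, which act as token anchors).  Rules violating phase
    constraints are rejected with a line-numbered error.
    """
    path = Path(path)
    if not path.is_file():
        raise RuleError(f"rule file not found: {path}")
    raw_lines = path.read_text(encoding="utf-8").splitlines()
    kept: list[tuple[int, str]] = []  # (original line number, line)
    for n, line in enumerate(raw_lines, start=1):
        if line.lstrip().startswith("#") or not line.strip():
            continue
        kept.append((n, line))
    if not kept:
        return RuleSet(phase=phase, rules=(), provenance=str(path))
    header_no, header = kept[0]
    reader = csv.DictReader(
        io.StringIO("\n".join([header] + [l for _, l in kept[1:]]))
    )
    required = {"order", "pattern", "replacement"}
    if not required.issubset(set(reader.fieldnames or ())):
        raise RuleError(f"{path}:{header_no}: rule file must have columns {sorted(required)}")
    rules = []
    for (line_no, _), row in zip(kept[1:], reader):
        try:
            rules.append(
                RewriteRule(
                    order=int(row["order"]),
                    pattern=row["pattern"] if row["pattern"] is not None else "",
                    replacement=row["replacement"] or "",
                    phase=phase,
                )
            )
        except (RuleError, ValueError, TypeError) as exc:
            raise RuleError(f"{path}:{line_no}: {exc}") from None
    try:
        return RuleSet(phase=phase, rules=tuple(rules), provenance=str(path))
    except RuleError as exc:
        raise RuleError(f"{path}: {exc}") from None
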