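# Methods

## The model: ordered literal substitutions

Both normalization phases are driven by one primitive, the ordered literal
substring substitution.  There is deliberately no pattern language: each
rule replaces *all* occurrences of a fixed substring, rules fire strictly
in `order`, and a rule is applied exactly once per input.  This makes rule
order the single source of control and keeps the behaviour of a rule list
auditable — the same property that makes the approach workable for the
messy, convention-mixing unit strings found in harvested metadata.  The
cost is that correctness is a property of the *list*, not of any rule in
isolation: a longest-fragment-first discipline is required so that, e.g.,
`centimetersquared` is consumed before `metersquared`, and `percent` is
ordered after every fragment that merely contains it (the
`gram·per·centimeter…` trap).  A dedicated test re-sorts the rules
alphabetically and asserts that at least one mapping breaks, guarding
against an accidental sort ever destroying this property silently.

### Pseudounit phase

Processing of a raw string: Unicode NFKD (micro sign U+00B5 and Greek mu
U+03BC coincide; superscript digits become plain digits), lowercase,
collapse whitespace runs and pad one space on each end, apply the rules in
order (re-collapsing whitespace after each rule so that space-anchored
patterns stay reliable), then delete whitespace and every character outside
`[a-z0-9]`.  The padding is an implementation device that lets rule
patterns use surrounding spaces as token anchors: `" m2 "` matches the
token `m2` but not the tail of `cm2`.  Digits are retained (a trailing `2`
may later become `squared`); hyphens survive *into* the rule stage so that
exponent tokens like `m-2` can be rewritten, and any hyphen left over is
deleted by the final character filter.

The default pseudo-phase list (~120 rules) covers, in order: symbol→word
substitutions, misspelling and variant-spelling repairs, spelled-out
exponent compounds (`square meter` and `squaremeter` → the ` m2 ` token —
ordered before plural rules because `metersquared` contains the substring
`meters`), plural→singular, and space-anchored abbreviation expansions
(exponent-bearing tokens before bare tokens).  Single-pass application
means chained repairs must be ordered explicitly (`metre`→`meter` precedes
`cenimeter`→`centimeter`); one residual misspelling (`cenimeter` arriving
via `cenimetre`) is caught again in the qudt phase.

### QUDT phase and finalization

Qudt-phase replacements are dash-delimited, mixed-case QUDT tokens
(`-CentiM-`, `-DEG_C-`).  Since pseudounits are dash-free, dashes mark
converted segments unambiguously.  Finalization strips leading/trailing
dashes, collapses dash runs, and keeps only the first `PER` token,
replacing later ones with plain dashes — QUDT codes use a single `PER` as
the numerator/denominator divider (`GM-PER-M2-DAY`, not
`GM-PER-M2-PER-DAY`).  A leading `PER` counts as the first (codes like
`PER-M2` are legitimate).  Finalization is idempotent and never touches
underscores: concept qualifiers (`DEG_C`, `GAL_US`) are produced only as
whole replacement tokens and are never synthesized or split.

Candidate/vocabulary comparison is case-sensitive exact match on the
finalized code.  Unmatched candidates are values, not errors: they are kept
for diagnostics and written to the sidecar candidate-units list ordered by
use count.  No on-the-fly derived-unit synthesis is attempted — a candidate
absent from the vocabulary stays unmatched.

Rule counts are data, not constants: the bundled lists are authored to
cover the bundled vocabulary and the canonical examples, and externally
curated lists in the same file dialect (`order,pattern,replacement` CSV,
`#` comments) can be dropped in via `--pseudo-rules` / `--qudt-rules`.

## Vocabulary and conversion

The vocabulary is a flat snapshot table, one row per unit, with the QUDT
dimension vector in its canonical eight-letter notation
(`A0E0L-2I0M1H0T0D0`; halves use `dot`, e.g. `T-0dot5`).  Exponents are
stored as exact rationals so vector equality — the guard for conversion —
is exact, never a float comparison.  SI parameters define
`si = multiplier · value + offset` (offset nonzero only for affine units
such as Celsius); conversion between compatible units is
`y = (m_a·x + b_a − b_b)/m_b` and round-trips to ≲1e-9 relative error.
Units lacking a published vector or multiplier load with those fields
absent and refuse to convert — the package never invents conversion
factors.  The bundled snapshot (~60 units spanning mass, length, area,
volume, time, temperature, concentration, pressure, energy and
dimensionless ratios) is transcribed from QUDT v2.1.25, including that
release's pattern-inconsistent legacy code `MicroG-PER-CentiM2`, loaded as
published and excluded from the label round-trip manifest.  The offline
Turtle importer regenerates snapshots from official releases so the runtime
library needs no RDF stack.

## Lookup table and resolution order

The build adds one row per successfully mapped distinct raw form (use
counts summed per form, not pooled across forms sharing a pseudounit), one
row per vocabulary unit keyed by its own code, one row per successfully
mapped corpus pseudounit, and one row per UCUM alias strictly longer than
two characters (shorter codes collide across systems: `m` could be metre or
milli-something).  Conflicting enrichment for the same (key, kind) is a
build error listing the conflicts.  Resolution order is raw key (trimmed,
case-sensitive — `mg` vs `MG` overloading makes folding unsafe at this
layer), QUDT code, UCUM alias, pseudounit key, then the full rewrite
pipeline; the first hit wins and is recorded as the match path.
Serialization sorts records and formats floats with `repr`, so a rebuild
from identical inputs is byte-identical; the in-memory build timestamp is
deliberately not serialized for this reason.

## EML annotation

Only EML 2.2+ documents are accepted (annotation elements entered the
schema at 2.2); older versions raise rather than being silently upgraded.
For each attribute-level `standardUnit`/`customUnit` that resolves, an
`<annotation>` with a property URI and the QUDT unit URI is appended inside
the attribute element (last position, matching the EML attribute content
model).  The default predicate is QUDT's `hasUnit`
(`http://qudt.org/schema/qudt/hasUnit`, label "has unit"); this default is
a package decision, overridable in configuration, since any schema-valid
predicate URI works in the triple.  Annotation is idempotent, never edits
the source tree, optionally bumps the trailing integer of `packageId`, and
optionally adds deterministic position-based `id` attributes.  Validation
tests run against a bundled *synthetic* reduced schema covering the
document structures this package reads and writes; it mirrors the official
EML 2.2 element order but is not the official multi-file schema
distribution.

## Synthetic corpus: what it emulates, and what it does not

The generator emulates the structure of harvested unit corpora: a small set
of underlying units rendered in several surface styles (symbolic `g/m2`,
spaced symbolic, spelled-out plural and singular, camelCase,
negative-exponent `g m-2 d-1`, and misspelled variants drawn from a fixed
list), Zipf-distributed use counts (default exponent 1.5 — across 20 seeds
the top 10 of 200 distinct forms carry ≥ 84% of instances, comfortably
reproducing the "few units dominate uses" skew), a junk fraction (default
0.10) of non-unit strings (missing-value codes, site labels, dates)
verified unresolvable at generation time and kept as singletons, and three
organization labels with unequal weights, with widely used forms assigned
to multiple organizations.  Identical seeds give identical corpora.

Because every true variant is by construction a form the default rules
cover, passing recovery tests demonstrates that the pipeline is *correct on
its covered grammar* (zero wrong codes, instance match ≥ 90% at 10% junk) —
it does not demonstrate coverage of the long tail of conventions in real
repositories, where distinct-form match rates around 10–15% against
instance rates above 90% are the realistic regime.  The generator does not
model repository-specific vocabularies or the correctness of a unit for its
measurement; organizations are opaque labels.

## Problem sizes and numerical choices

Default study conditions: 200 distinct forms, Zipf exponent 1.5, junk
fraction 0.10, 61-unit vocabulary — chosen as a desk-scale emulation of the
corpus skew; tests and the acceptance script run in seconds at these sizes.
Conversion round-trip tolerance is 1e-9 relative; percentages are reported
to 0.1%.  Ties between overlapping rule patterns at the same position are
resolved purely by rule order (the earlier rule rewrites the whole string
first).  Degenerate inputs are defined, not errors: empty strings normalize
to the empty pseudounit ("nothing unit-like survived"), unknown text passes
through the qudt phase untouched, and unmatched lookups are ordinary
values.

## Known limitations

- The bundled rule lists are smaller than production-scale curated lists;
  coverage outside the bundled vocabulary requires dropping in larger rule
  files and a full vocabulary snapshot.
- Single-pass rule application cannot chain repairs that were not
  explicitly ordered; unanticipated misspelling × word-order combinations
  may fail to normalize.
- UCUM aliases are used as opaque keys; UCUM's grammar is not parsed, and
  ambiguous (multi-unit) aliases are simply not used as direct match keys.
- No substance-aware conversions (molar ↔ mass), no quantity-kind
  reasoning, and no subject/context annotations — the unit, not the
  measurement, is the scope.
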