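# unitlink

Link *ad hoc* unit strings in ecological metadata to units in the QUDT
ontology.

Environmental data repositories accumulate free-text unit descriptions:
`gm/m2`, `g/m2`, `gm-2`, `g/m^2`, `g.m-2` and `gramPerMeterSquared` are all
human-readable spellings of one unit, but none is machine-interpretable.
`unitlink` connects such strings to a single ontology concept
(`unit:GM-PER-M2`, `http://qudt.org/vocab/unit/GM-PER-M2`), which brings
along labels, definitions, dimension vectors and SI conversion factors, and
lets metadata documents be annotated with machine-readable unit URIs.  It is
aimed at data managers and repository engineers curating Ecological Metadata
Language (EML) documents.

## Method

Two ordered sets of literal substring substitutions do the work:

1. **Pseudounit phase.** A raw string is Unicode-normalized, lowercased, and
   run through ordered rules that replace symbols with words (`/` → `per`,
   `%` → `percent`, `µ` → `micro`), fix word order (`square meter` →
   `metersquared`), repair common misspellings (`cenimeter`, `celcius`) and
   expand abbreviations (`g` → `gram`, `m2` → `metersquared`); whitespace
   and residual symbols are then deleted.  The result is a *pseudounit* —
   lowercase, no spaces or symbols — that groups surface variants:
   all six spellings above become `grampermetersquared`.

2. **QUDT phase.** A second ordered rule set rewrites pseudounit fragments
   into dash-delimited, QUDT-cased tokens.  Because pseudounits cannot
   contain dashes, converted segments are visibly distinct while the rules
   run.  For `grampermetersquaredperday`:

   | step | rule | result |
   |------|------|--------|
   | 1 | `metersquared` → `-M2-` | `gramper-M2-perday` |
   | 2 | `day` → `-DAY-` | `gramper-M2-per-DAY-` |
   | 3 | `gram` → `-GM-` | `-GM-per-M2-per-DAY-` |
   | 4 | `per` → `-PER-` | `-GM--PER--M2--PER--DAY-` |

   Finalization strips outer dashes, collapses dash runs and keeps only the
   first `PER` divider (`GM-PER-M2-PER-DAY` → `GM-PER-M2-DAY`, a QUDT
   unit).  Rule *order* is the only control mechanism: longer fragments fire
   first, so `grampercentimetersquared` maps to `GM-PER-CentiM2` and never
   spuriously matches the embedded `percent`.

Matched units feed an enriched **lookup table** keyed by raw form,
pseudounit, QUDT code and UCUM alias (aliases of ≤ 2 characters are excluded
as ambiguous), with label, URI, dimension vector and SI multiplier/offset
columns.  Conversion between units is gated on **exact dimension-vector
equality** over the eight QUDT basis dimensions (amount of substance,
electric current, length, luminous intensity, mass, thermodynamic
temperature, time, dimensionless):
`y = (m_from · x + b_from − b_to) / m_to`.  Milligrams per litre therefore
never converts to millimoles per litre — that requires the substance's
molar mass, which belongs to the measurement, not the unit.

The package bundles a snapshot of ~60 units transcribed from QUDT v2.1.25;
`scripts/qudt_ttl_to_snapshot.py` converts any official QUDT Turtle release
into the same snapshot format for full-vocabulary use.

## Worked example

```sh
$ unitlink map "g m-2"
GM-PER-M2

$ unitlink normalize "grams per square meter"
grampermetersquared

$ unitlink convert 0 --from DEG_C --to K
273.15

$ unitlink resolve "kPa"
{"match_path": "ucum", "matched": true, "qudt_code": "KiloPA", "query": "kPa", "uri": "http://qudt.org/vocab/unit/KiloPA"}
```

`map` prints the QUDT code reached by the two rewrite phases; `resolve`
reports which lookup path matched (raw key, QUDT code, UCUM alias, or
rewrite).  A synthetic corpus emulating real repository skew — Zipf-
distributed use counts, several surface variants per unit, 10% junk strings
concentrated in singletons — can be generated and tabulated:

```sh
$ unitlink simulate --seed 1 --out corpus.csv
wrote 248 entries (108717 instances) to corpus.csv
$ unitlink stats corpus.csv
{"distinct_match_percent": 90.0, "instance_match_percent": 100.0, "n_distinct": 200,
 "n_distinct_matched": 180, "n_instances_matched": 108697, ...}
```

The 90% vs ~100% gap is the signature of skewed corpora: junk strings
inflate the count of distinct unmatched forms but contribute almost no
instances.  `unitlink annotate doc.xml --out annotated.xml` adds
RDF-triple-style `<annotation>` elements to an EML 2.2 document, e.g. for an
attribute measured in `micromolesPerLiter`:

```xml
<annotation>
  <propertyURI label="has unit">http://qudt.org/schema/qudt/hasUnit</propertyURI>
  <valueURI label="micromole per litre">http://qudt.org/vocab/unit/MicroMOL-PER-L</valueURI>
</annotation>
```

`unitlink serve` exposes the same lookup as a read-only HTTP endpoint
(`GET /?rawunit=g/m2&returntype=json|xml|html`).

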