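"""Offline importer: QUDT Turtle release file to a flat snapshot table.

The core library only ever reads the flat snapshot-table format, so it
needs no RDF stack at runtime.  This importer (and its wrapper script
``scripts/qudt_ttl_to_snapshot.py``) converts an official QUDT units
release — e.g. the v2.1.25 ``VOCAB_QUDT-UNITS-ALL`` Turtle file — into a
snapshot usable by :func:`unitlink.vocab.load_vocabulary`.  rdflib is
imported lazily and is only required when this module is used.
"""

from __future__ import annotations

import csv
from pathlib import Path

__all__ = ["ttl_to_snapshot"]

_QUDT = "http://qudt.org/schema/qudt/"
_UNIT_PREFIX = "http://qudt.org/vocab/unit/"


def ttl_to_snapshot(ttl_path: str | Path, out_path: str | Path, version: str = "") -> int:
    """Convert a QUDT units Turtle file to a snapshot table.

    Returns the number of unit rows written.  Units lacking a dimension
    vector or multiplier get empty cells (they load, but cannot convert).
    """
    import rdflib
    from rdflib.namespace import RDF, RDFS

    QUDT = rdflib.Namespace(_QUDT)
    graph = rdflib.Graph()
    graph.parse(str(ttl_path), format="turtle")

    rows = []
    for subject in sorted(set(graph.subjects(RDF.type, QUDT.Unit))):
        uri = str(subject)
        if not uri.startswith(_UNIT_PREFIX):
            continue
        code = uri[len(_UNIT_PREFIX):]

        def first(pred):
            for obj in graph.objects(subject, pred):
                return obj
            return None

        label = None
        for obj in graph.objects(subject, RDFS.label):
            if getattr(obj, "language", None) in (None, "en"):
                label = str(obj)
                if getattr(obj, "language", None) == "en":
                    break
        dim = first(QUDT.hasDimensionVector)
        dim_code = str(dim).rsplit("/", 1)[-1] if dim is not None else ""
        multiplier = first(QUDT.conversionMultiplier)
        offset = first(QUDT.conversionOffset)
        ucum = sorted(str(o) for o in graph.objects(subject, QUDT.ucumCode))
        kinds = sorted(
            str(o).rsplit("/", 1)[-1] for o in graph.objects(subject, QUDT.hasQuantityKind)
        )
        description = first(QUDT.plainTextDescription)
        rows.append(
            [
                code,
                uri,
                label or code,
                dim_code,
                str(multiplier) if multiplier is not None else "",
                str(offset) if offset is not None else "0",
                ";".join(ucum),
                ";".join(kinds),
                str(description) if description is not None else "",
            ]
        )

    with Path(out_path).open("w", encoding="utf-8", newline="") as fh:
        if version:
            fh.write(f"# version: {version}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            [
                "code",
                "uri",
                "label",
                "dimension_vector",
                "si_multiplier",
                "si_offset",
                "ucum",
                "quantity_kinds",
                "description",
            ]
        )
        writer.writerows(rows)
    return len(rows)
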