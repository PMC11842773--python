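#!/usr/bin/env python
"""Offline importer: convert a QUDT units Turtle release to a snapshot table.

Download an official QUDT units vocabulary file (e.g. the v2.1.25
``VOCAB_QUDT-UNITS-ALL-v2.1.25.ttl``) and run::

    python scripts/qudt_ttl_to_snapshot.py units.ttl snapshot.csv --version 2.1.25

The resulting snapshot loads with ``unitlink.load_vocabulary`` and can be
passed to every CLI subcommand via ``--vocab``.  Requires rdflib.
"""

import argparse

from unitlink.ttl_import import ttl_to_snapshot


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("ttl", help="QUDT units Turtle file")
    parser.add_argument("out", help="Snapshot table output path")
    parser.add_argument("--version", default="", help="Version tag to record")
    args = parser.parse_args()
    n = ttl_to_snapshot(args.ttl, args.out, version=args.version)
    print(f"wrote {n} unit rows to {args.out}")


if __name__ == "__main__":
    main()
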