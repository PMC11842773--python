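"""Minimal read-only lookup service over a built lookup table.

Mirrors the shape of a units web service: one stateless operation taking
``rawunit`` and ``returntype`` query parameters and returning the matched
QUDT unit's code, URI, label, dimension vector and SI multiplier in JSON,
XML or HTML, including the EML-ready ``<annotation>`` fragment for matched
units.  A small WSGI application exposes it over HTTP GET; the CLI ``serve``
subcommand runs it with the stdlib server.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import dataclass
from urllib.parse import parse_qs

from lxml import etree

from .eml import annotation_fragment
from .lookup import Resolver

__all__ = ["RETURN_TYPES", "LookupResponse", "ServiceError", "handle_lookup", "create_wsgi_app"]

RETURN_TYPES = ("json", "xml", "html")

_CONTENT_TYPES = {
    "json": "application/json; charset=utf-8",
    "xml": "application/xml; charset=utf-8",
    "html": "text/html; charset=utf-8",
}


class ServiceError(ValueError):
    """Client error: empty query or unknown return type."""


@dataclass(frozen=True)
class LookupResponse:
    query: str
    matched: bool
    returntype: str
    qudt_code: str | None = None
    uri: str | None = None
    label: str | None = None
    dimension_vector: str | None = None
    si_multiplier: float | None = None
    ucum: str | None = None
    match_path: str = "unmatched"
    annotation: str | None = None

    def fields(self) -> dict:
        out = {"query": self.query, "matched": self.matched, "match_path": self.match_path}
        if self.matched:
            out.update(
                qudt_code=self.qudt_code,
                uri=self.uri,
                label=self.label,
                dimension_vector=self.dimension_vector,
                si_multiplier=self.si_multiplier,
                ucum=self.ucum,
                annotation=self.annotation,
            )
        return out

    @property
    def content_type(self) -> str:
        return _CONTENT_TYPES[self.returntype]

    def body(self) -> str:
        fields = self.fields()
        if self.returntype == "json":
            return json.dumps(fields, sort_keys=True, ensure_ascii=False, indent=2)
        if self.returntype == "xml":
            root = etree.Element("lookupResponse")
            for key, value in sorted(fields.items()):
                child = etree.SubElement(root, key)
                if value is not None:
                    child.text = str(value)
            return etree.tostring(root, pretty_print=True, encoding="unicode")
        rows = "".join(
            f"<tr><th>{_html.escape(k)}</th><td>{_html.escape(str(v)) if v is not None else ''}</td></tr>"
            for k, v in sorted(fields.items())
        )
        return (
            "<!DOCTYPE html><html><head><title>unit lookup</title></head>"
            f"<body><table>{rows}</table></body></html>"
        )


def handle_lookup(rawunit: str, returntype: str = "json", resolver: Resolver | None = None) -> LookupResponse:
    """Resolve one raw unit string and package the result for the service.

    Raises :class:`ServiceError` for an empty ``rawunit`` or a return type
    outside ``json``, ``xml``, ``html``.
    """
    if returntype not in RETURN_TYPES:
        raise ServiceError(
            f"unknown returntype {returntype!r}; allowed values: {', '.join(RETURN_TYPES)}"
        )
    if not rawunit or not rawunit.strip():
        raise ServiceError("rawunit must be nonempty")
    if resolver is None:
        resolver = Resolver.default()
    result = resolver.resolve(rawunit)
    if not result.matched:
        return LookupResponse(query=rawunit, matched=False, returntype=returntype)
    unit = result.matched_unit
    return LookupResponse(
        query=rawunit,
        matched=True,
        returntype=returntype,
        qudt_code=unit.code,
        uri=unit.uri,
        label=unit.label,
        dimension_vector=unit.dimension_vector.render() if unit.dimension_vector else None,
        si_multiplier=unit.si_multiplier,
        ucum=";".join(unit.ucum_codes),
        match_path=result.match_path,
        annotation=annotation_fragment(unit),
    )


def create_wsgi_app(resolver: Resolver):
    """WSGI application serving GET requests with rawunit/returntype params."""

    def app(environ, start_response):
        if environ.get("REQUEST_METHOD", "GET") != "GET":
            start_response("405 Method Not Allowed", [("Content-Type", "text/plain")])
            return [b"GET only\n"]
        params = parse_qs(environ.get("QUERY_STRING", ""))
        rawunit = (params.get("rawunit") or [""])[0]
        returntype = (params.get("returntype") or ["json"])[0]
        try:
            response = handle_lookup(rawunit, returntype, resolver)
        except ServiceError as exc:
            body = json.dumps({"error": str(exc)}).encode("utf-8")
            start_response(
                "400 Bad Request", [("Content-Type", "application/json; charset=utf-8")]
            )
            return [body]
        body = response.body().encode("utf-8")
        start_response("200 OK", [("Content-Type", response.content_type)])
        return [body]

    return app
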