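"""Variant annotation via pluggable backends.

Annotation attributes are addressed by hierarchical dotted field names
(e.g. ``cadd.gene.prot.domain``) and fetched per HGVSg identifier.  Two
backends implement the same contract: an offline fixture backend reading a
local JSON file (used throughout the test suite), and a batch HTTP client
for MyVariant-style services (never exercised in tests; the run degrades
gracefully to an unannotated VCF when the service is unreachable).
"""

from __future__ import annotations

import json
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path

from .hgvs import HgvsTriple
from .vcfio import VcfRecord, encode_info_value, sanitize_info_key

__all__ = [
    "AnnotationError",
    "AnnotationRecord",
    "FixtureBackend",
    "HttpBackend",
    "fetch",
    "inject_info",
]

_FIELD_RE = re.compile(r"^[A-Za-z0-9_]+(\.[A-Za-z0-9_]+)*$")


class AnnotationError(RuntimeError):
    """Backend unreachable or misconfigured."""


@dataclass(frozen=True)
class AnnotationRecord:
    hgvs_g: str
    values: dict[str, str] = field(default_factory=dict)


class FixtureBackend:
    """Offline backend reading a JSON file keyed by HGVSg id.

    File format: ``{"chr1:g.100A>G": {"cadd.phred": 22.1, ...}, ...}``.
    """

    def __init__(self, path: str | Path):
        with open(path) as fh:
            self._data: dict[str, dict] = json.load(fh)

    def query(self, ids: list[str], fields: list[str]) -> list[dict[str, str]]:
        out = []
        for hgvs_g in ids:
            row = self._data.get(hgvs_g, {})
            out.append({f: row[f] for f in fields if f in row})
        return out


class HttpBackend:
    """Batch HTTP client (100 ids per request, one retry per batch)."""

    def __init__(self, url: str, batch_size: int = 100, timeout: float = 10.0):
        self.url = url
        self.batch_size = batch_size
        self.timeout = timeout

    def _post(self, ids: list[str], fields: list[str]) -> list[dict]:
        payload = json.dumps({"ids": ids, "fields": fields}).encode()
        req = urllib.request.Request(
            self.url, data=payload,
            headers={"Content-Type": "application/json"})
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return json.loads(resp.read().decode())

    def query(self, ids: list[str], fields: list[str]) -> list[dict[str, str]]:
        out: list[dict] = []
        for i in range(0, len(ids), self.batch_size):
            batch = ids[i:i + self.batch_size]
            try:
                rows = self._post(batch, fields)
            except (urllib.error.URLError, OSError, ValueError):
                try:  # retry once
                    rows = self._post(batch, fields)
                except (urllib.error.URLError, OSError, ValueError) as exc:
                    raise AnnotationError(
                        f"annotation service unreachable: {exc}") from exc
            if len(rows) != len(batch):
                raise AnnotationError("annotation service returned wrong "
                                      "number of records")
            out.extend(rows)
        return [{f: row[f] for f in fields if f in row} for row in out]


def fetch(backend, ids: list[str], fields: list[str]) -> list[AnnotationRecord]:
    """One AnnotationRecord per id; variants missing from the source yield
    empty mappings."""
    for f in fields:
        if not _FIELD_RE.match(f):
            raise ValueError(f"malformed annotation field name: {f!r}")
    if not fields or not ids:
        return [AnnotationRecord(i) for i in ids]
    rows = backend.query(list(ids), list(fields))
    return [AnnotationRecord(i, {k: str(v) for k, v in row.items()})
            for i, row in zip(ids, rows)]


def inject_info(record: VcfRecord, ann: AnnotationRecord,
                triple: HgvsTriple) -> VcfRecord:
    """Return the record with HGVS keys plus annotation fields added to
    INFO (pure decoration: all other columns are untouched)."""
    info = [(k, v) for k, v in record.info
            if k not in ("HGVSG", "HGVSC", "HGVSP")]
    hgvs: list[tuple[str, str | None]] = [
        ("HGVSG", encode_info_value(triple.hgvs_g))]
    if triple.hgvs_c:
        hgvs.append(("HGVSC", encode_info_value(triple.hgvs_c)))
    if triple.hgvs_p:
        hgvs.append(("HGVSP", encode_info_value(triple.hgvs_p)))
    extra = [(sanitize_info_key(k), encode_info_value(str(v)))
             for k, v in ann.values.items()]
    return replace(record, info=tuple(hgvs + info + extra))
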