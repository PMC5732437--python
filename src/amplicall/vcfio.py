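"""VCF 4.2 and TSV serialization.

The writer emits sorted, header-complete single-sample VCF with pair-level
FORMAT fields DP (merged pairs covering the locus), VD (pairs supporting
the variant) and AF (VD/DP).  INFO carries the HGVS triple, supporting
amplicons, MNP phasing links and any annotation fields (dotted names
preserved; values percent-encoded where they contain VCF-reserved
characters).  The reader is lossless for everything the writer emits and
preserves foreign INFO keys and their header declarations, so
write→read→write is byte-stable.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .calling import CallSet
from .hgvs import HgvsTriple

__all__ = [
    "VcfError",
    "VcfRecord",
    "VcfDocument",
    "encode_info_value",
    "decode_info_value",
    "sanitize_info_key",
    "write_vcf",
    "write_records",
    "read_vcf",
    "write_tsv",
]


class VcfError(ValueError):
    pass


# characters that break VCF INFO syntax; '%' first so decoding round-trips
_RESERVED = "%;,=\t\n\r "


def encode_info_value(value: str) -> str:
    for ch in _RESERVED:
        value = value.replace(ch, f"%{ord(ch):02X}")
    return value


def decode_info_value(value: str) -> str:
    return re.sub("%([0-9A-Fa-f]{2})",
                  lambda m: chr(int(m.group(1), 16)), value)


def sanitize_info_key(key: str) -> str:
    """Dots are kept (hierarchical annotation names); anything outside
    [A-Za-z0-9_.] becomes an underscore."""
    return re.sub(r"[^A-Za-z0-9_.]", "_", key)


@dataclass(frozen=True)
class VcfRecord:
    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    qual: str
    filter: str
    info: tuple[tuple[str, str | None], ...]  # (key, encoded value|flag)
    fmt: tuple[tuple[str, str], ...] = ()     # single sample

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise VcfError("ref/alt must be non-empty")
        if self.pos < 1:
            raise VcfError("pos must be >= 1")

    def info_get(self, key: str, decode: bool = True) -> str | None:
        for k, v in self.info:
            if k == key:
                if v is None:
                    return ""
                return decode_info_value(v) if decode else v
        return None

    def fmt_get(self, key: str) -> str | None:
        for k, v in self.fmt:
            if k == key:
                return v
        return None

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VcfDocument:
    """Records plus the header metadata needed to re-emit them."""

    records: list[VcfRecord]
    sample: str = "SAMPLE"
    contigs: dict[str, int] = field(default_factory=dict)
    info_meta: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    filter_meta: dict[str, str] = field(default_factory=dict)
    format_meta: dict[str, tuple[str, str, str]] = field(default_factory=dict)


_STANDARD_FORMAT = {
    "DP": ("1", "Integer", "Merged read pairs covering the locus"),
    "VD": ("1", "Integer", "Merged read pairs supporting the variant"),
    "AF": ("1", "Float", "Variant allele frequency (VD/DP)"),
}

_STANDARD_INFO = {
    "HGVSG": ("1", "String", "HGVS genomic name"),
    "HGVSC": ("1", "String", "HGVS coding name on the selected transcript"),
    "HGVSP": ("1", "String", "Predicted protein consequence"),
    "GENE": ("1", "String", "Gene symbol of the selected transcript"),
    "AMPS": (".", "String", "Amplicons supporting the call"),
    "MNP_PARENT": ("0", "Flag", "Compound in-phase (delins) parent record"),
    "MNP_LINK": ("1", "String", "Phasing group shared by parent and constituents"),
}

_STANDARD_FILTERS = {
    "LowVAF": "Variant allele frequency below threshold",
    "LowDepth": "Supporting pair count below threshold",
}


def write_records(doc: VcfDocument, path: str | Path) -> None:
    """Serialize a VcfDocument; records must be strictly sorted by
    (chrom, pos, ref, alt) with no duplicates."""
    prev = None
    for rec in doc.records:
        if prev is not None and rec.key() <= prev:
            raise VcfError(f"records unsorted or duplicated at {rec.key()}")
        prev = rec.key()
    lines = ["##fileformat=VCFv4.2"]
    for name, length in doc.contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    for name, desc in doc.filter_meta.items():
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    for key, (num, typ, desc) in doc.info_meta.items():
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},'
                     f'Description="{desc}">')
    for key, (num, typ, desc) in doc.format_meta.items():
        lines.append(f'##FORMAT=<ID={key},Number={num},Type={typ},'
                     f'Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + doc.sample)
    for rec in doc.records:
        info = ";".join(k if v is None else f"{k}={v}" for k, v in rec.info)
        fmt_keys = ":".join(k for k, _ in rec.fmt)
        fmt_vals = ":".join(v for _, v in rec.fmt)
        lines.append("\t".join([
            rec.chrom, str(rec.pos), rec.id, rec.ref, rec.alt, rec.qual,
            rec.filter, info or ".", fmt_keys, fmt_vals]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(callset: CallSet, triples: dict[tuple, HgvsTriple],
              annotations: dict[tuple, dict[str, str]],
              path: str | Path, contigs: dict[str, int] | None = None,
              genes: dict[tuple, str] | None = None) -> VcfDocument:
    """Write a CallSet as annotated VCF.

    ``triples`` / ``annotations`` / ``genes`` map the variant key
    (chrom, pos, ref, alt) to the HGVS triple, the dotted-field annotation
    mapping and the gene symbol.  Returns the document that was written.
    """
    genes = genes or {}
    ann_keys: list[str] = []
    records: list[VcfRecord] = []
    for call in sorted(callset.calls, key=lambda c: c.variant.key()):
        v = call.variant
        k = v.key()
        triple = triples.get(k)
        info: list[tuple[str, str | None]] = []
        if triple is not None:
            info.append(("HGVSG", encode_info_value(triple.hgvs_g)))
            if triple.hgvs_c:
                info.append(("HGVSC", encode_info_value(triple.hgvs_c)))
            if triple.hgvs_p:
                info.append(("HGVSP", encode_info_value(triple.hgvs_p)))
        if k in genes:
            info.append(("GENE", encode_info_value(genes[k])))
        if call.amplicons:
            info.append(("AMPS", ",".join(
                encode_info_value(a) for a in call.amplicons)))
        if call.is_mnp_parent:
            info.append(("MNP_PARENT", None))
        if call.mnp_link:
            info.append(("MNP_LINK", encode_info_value(call.mnp_link)))
        for fld, value in (annotations.get(k) or {}).items():
            key = sanitize_info_key(fld)
            if key not in ann_keys:
                ann_keys.append(key)
            info.append((key, encode_info_value(str(value))))
        records.append(VcfRecord(
            chrom=v.chrom, pos=v.pos, id=".", ref=v.ref, alt=v.alt,
            qual=".", filter=";".join(call.filters) or "PASS",
            info=tuple(info),
            fmt=(("DP", str(call.depth_pairs)),
                 ("VD", str(call.alt_pairs)),
                 ("AF", f"{call.vaf:.6g}"))))
    if contigs is None:
        contigs = {}
        for rec in records:
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0),
                                     rec.pos + len(rec.ref) + 1000)
    info_meta = dict(_STANDARD_INFO)
    for key in ann_keys:
        info_meta[key] = ("1", "String", f"Annotation field {key}")
    doc = VcfDocument(records=records, sample=callset.sample,
                      contigs=dict(contigs), info_meta=info_meta,
                      filter_meta=dict(_STANDARD_FILTERS),
                      format_meta=dict(_STANDARD_FORMAT))
    write_records(doc, path)
    return doc


_META_RE = re.compile(r"^##(\w+)=<(.+)>$")


def _parse_meta_fields(body: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    for m in re.finditer(r'(\w+)=("[^"]*"|[^,]+)', body):
        val = m.group(2)
        if val.startswith('"'):
            val = val[1:-1]
        fields[m.group(1)] = val
    return fields


def read_vcf(path: str | Path) -> VcfDocument:
    """Parse a VCF file into a VcfDocument; malformed lines raise VcfError
    naming the line number."""
    doc = VcfDocument(records=[])
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                m = _META_RE.match(line)
                if not m:
                    continue  # e.g. ##fileformat=VCFv4.2
                kind, body = m.groups()
                fields = _parse_meta_fields(body)
                if kind == "contig":
                    doc.contigs[fields["ID"]] = int(fields.get("length", 0))
                elif kind == "INFO":
                    doc.info_meta[fields["ID"]] = (
                        fields.get("Number", "1"), fields.get("Type", "String"),
                        fields.get("Description", ""))
                elif kind == "FILTER":
                    doc.filter_meta[fields["ID"]] = fields.get("Description", "")
                elif kind == "FORMAT":
                    doc.format_meta[fields["ID"]] = (
                        fields.get("Number", "1"), fields.get("Type", "String"),
                        fields.get("Description", ""))
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 8:
                    raise VcfError(f"line {lineno}: truncated #CHROM header")
                if len(cols) >= 10:
                    doc.sample = cols[9]
                saw_header = True
                continue
            if not saw_header:
                raise VcfError(f"line {lineno}: record before #CHROM header")
            cols = line.split("\t")
            if len(cols) < 8:
                raise VcfError(f"line {lineno}: expected >= 8 columns, "
                               f"got {len(cols)}")
            try:
                info: list[tuple[str, str | None]] = []
                if cols[7] != ".":
                    for item in cols[7].split(";"):
                        if "=" in item:
                            k, v = item.split("=", 1)
                            info.append((k, v))
                        else:
                            info.append((item, None))
                fmt: tuple[tuple[str, str], ...] = ()
                if len(cols) >= 10:
                    fmt = tuple(zip(cols[8].split(":"), cols[9].split(":")))
                doc.records.append(VcfRecord(
                    chrom=cols[0], pos=int(cols[1]), id=cols[2], ref=cols[3],
                    alt=cols[4], qual=cols[5], filter=cols[6],
                    info=tuple(info), fmt=fmt))
            except (ValueError, IndexError) as exc:
                raise VcfError(f"line {lineno}: {exc}") from exc
    if not saw_header:
        raise VcfError("no #CHROM header line found")
    return doc


_TSV_CORE = ["sample", "chrom", "pos", "ref", "alt", "gene", "transcript",
             "hgvs_g", "hgvs_c", "hgvs_p", "dp", "vd", "af"]


def write_tsv(records: list[VcfRecord], path: str | Path,
              sample: str, ann_fields: list[str] | None = None) -> None:
    """Flat per-record table for spreadsheets: core columns then one column
    per requested annotation field, in request order."""
    ann_fields = [sanitize_info_key(f) for f in (ann_fields or [])]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n",
                            quoting=csv.QUOTE_MINIMAL)
        writer.writerow(_TSV_CORE + ann_fields)
        for rec in records:
            hgvs_c = rec.info_get("HGVSC") or ""
            transcript = hgvs_c.split(":", 1)[0] if ":" in hgvs_c else ""
            row = [
                sample, rec.chrom, str(rec.pos), rec.ref, rec.alt,
                rec.info_get("GENE") or "", transcript,
                rec.info_get("HGVSG") or "", hgvs_c,
                rec.info_get("HGVSP") or "",
                rec.fmt_get("DP") or "", rec.fmt_get("VD") or "",
                rec.fmt_get("AF") or "",
            ]
            row += [rec.info_get(f) or "" for f in ann_fields]
            writer.writerow(row)
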