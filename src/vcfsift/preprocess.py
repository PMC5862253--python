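"""Step 1 — pre-processing.

Discovers every filterable field in a VCF (core columns, INFO keys, FORMAT
keys, and VEP CSQ sub-fields), normalizes missing values ("." and the empty
string become the canonical marker ``"nan"``), expands CSQ annotation strings
into one value list per sub-field, and persists the selected columns as a
table under a working directory for the indexing and filtering steps.

Core columns are exposed as five composite fields, mirroring how the indexes
are grouped: ``CHROM+POS``, ``ID``, ``REF+ALT``, ``QUAL``, ``FILTER``.

Every cell is a *list* of normalized strings: multi-valued INFO fields keep
all their values, FORMAT fields hold one slot per sample, and CSQ sub-fields
hold one value per transcript block.  Downstream filters use any-match
semantics over these lists; a cell counts as missing only when *all* its
values are missing.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, CsqError, StateError
from .vcf_model import (
    MISSING,
    FieldDescriptor,
    Origin,
    ValueType,
    VariantKey,
    VariantRecord,
    VcfReader,
    open_vcf,
)

MANIFEST_NAME = "manifest.json"
TABLE_NAME = "table.jsonl"

#: The five core composite fields always discoverable in any VCF.
CORE_FIELD_NAMES = ("CHROM+POS", "ID", "REF+ALT", "QUAL", "FILTER")

_VCF_TYPE_MAP = {
    "Integer": ValueType.INTEGER,
    "Float": ValueType.FLOAT,
    "String": ValueType.STRING,
    "Flag": ValueType.FLAG,
    "Character": ValueType.CHAR,
}


def normalize(value: str | None) -> str:
    """Map source missing markers ("." and empty) to the canonical ``nan``."""
    if value is None or value in (".", ""):
        return MISSING
    return value


@dataclass(frozen=True)
class CsqSchema:
    """Ordered CSQ sub-field names exactly as declared after "Format: " in the
    CSQ header line; users see each as ``CSQ_<name>``."""

    subfields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.subfields:
            raise ValueError("CSQ schema must be non-empty")

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple("CSQ_" + s for s in self.subfields)


def expand_csq(
    csq_value: str, schema: CsqSchema, record_label: str = ""
) -> list[dict[str, str]]:
    """Expand one raw CSQ value into per-transcript sub-field maps.

    Transcript blocks are comma-separated; sub-values within a block are
    pipe-separated and matched positionally to the schema.  Short blocks are
    right-padded with the missing marker; over-long blocks are an error.
    """
    maps: list[dict[str, str]] = []
    for block in csq_value.split(","):
        parts = block.split("|")
        if len(parts) > len(schema.subfields):
            where = f" in record {record_label}" if record_label else ""
            raise CsqError(
                f"CSQ block has {len(parts)} sub-values but the schema declares "
                f"{len(schema.subfields)}{where}"
            )
        parts = parts + [""] * (len(schema.subfields) - len(parts))
        maps.append(
            {
                "CSQ_" + name: normalize(val)
                for name, val in zip(schema.subfields, parts)
            }
        )
    return maps


def _core_descriptors() -> list[FieldDescriptor]:
    return [
        FieldDescriptor("CHROM+POS", Origin.CORE, ValueType.STRING, "1",
                        "chromosome and 1-based position"),
        FieldDescriptor("ID", Origin.CORE, ValueType.STRING, "1",
                        "variant identifier"),
        FieldDescriptor("REF+ALT", Origin.CORE, ValueType.STRING, "A",
                        "reference and alternate alleles"),
        FieldDescriptor("QUAL", Origin.CORE, ValueType.FLOAT, "1",
                        "Phred-scaled quality"),
        FieldDescriptor("FILTER", Origin.CORE, ValueType.STRING, ".",
                        "filter status"),
    ]


def discover_fields(source: str | Path | VcfReader) -> list[FieldDescriptor]:
    """Return every filterable field of a VCF.

    Union of the five core composites, every declared *or observed* INFO key,
    every declared or observed FORMAT key, and — when a CSQ declaration with a
    "Format:" schema exists — one ``CSQ_<subfield>`` descriptor per sub-field
    in place of the bare ``CSQ`` key.  Keys used in the body but undeclared in
    the header are typed STRING with arity ".".
    """
    reader = source if isinstance(source, VcfReader) else open_vcf(source)
    close = not isinstance(source, VcfReader)
    try:
        header = reader.header
        observed_info: dict[str, None] = {}
        observed_fmt: dict[str, None] = {}
        for rec in reader:
            for k in rec.info:
                observed_info.setdefault(k)
            for k in rec.format_keys:
                observed_fmt.setdefault(k)
    finally:
        if close:
            reader.close()

    descriptors = _core_descriptors()
    names = {d.name for d in descriptors}
    csq_subs = header.csq_subfields()

    info_order = list(header.info_defs) + [
        k for k in observed_info if k not in header.info_defs
    ]
    for key in info_order:
        if key == "CSQ" and csq_subs:
            for sub in csq_subs:
                d = FieldDescriptor("CSQ_" + sub, Origin.CSQ, ValueType.STRING, ".",
                                    f"VEP {sub}")
                if d.name not in names:
                    descriptors.append(d)
                    names.add(d.name)
            continue
        defn = header.info_defs.get(key)
        vt = _VCF_TYPE_MAP.get(defn.type, ValueType.STRING) if defn else ValueType.STRING
        arity = defn.number if defn else "."
        desc = defn.description if defn else ""
        if vt is ValueType.FLAG and defn is None:
            vt = ValueType.STRING
        if key not in names:
            descriptors.append(FieldDescriptor(key, Origin.INFO, vt, arity, desc))
            names.add(key)

    fmt_order = list(header.format_defs) + [
        k for k in observed_fmt if k not in header.format_defs
    ]
    for key in fmt_order:
        defn = header.format_defs.get(key)
        vt = _VCF_TYPE_MAP.get(defn.type, ValueType.STRING) if defn else ValueType.STRING
        if vt is ValueType.FLAG:
            vt = ValueType.STRING  # flags are INFO-only
        arity = defn.number if defn else "."
        desc = defn.description if defn else ""
        name = key if key not in names else "FORMAT_" + key
        if name in names:
            continue
        descriptors.append(FieldDescriptor(name, Origin.FORMAT, vt, arity, desc))
        names.add(name)
    return descriptors


def _format_qual(rec: VariantRecord) -> str:
    return normalize(rec.qual_text)


def extract_cell(
    rec: VariantRecord,
    desc: FieldDescriptor,
    sample_names: Sequence[str],
    schema: CsqSchema | None,
    csq_maps: list[dict[str, str]] | None,
) -> list[str]:
    """Normalized value list of one field for one record.

    ``csq_maps`` is the per-record expansion of the CSQ value (or None when
    the record has no CSQ annotation); callers expand once per record and
    share the result across the selected CSQ sub-fields.
    """
    if desc.origin is Origin.CORE:
        if desc.name == "CHROM+POS":
            return [f"{rec.key.chrom}:{rec.key.pos}"]
        if desc.name == "ID":
            return [normalize(rec.id)]
        if desc.name == "REF+ALT":
            if not rec.alts:
                return [MISSING]
            return [f"{rec.ref}>{a}" for a in rec.alts]
        if desc.name == "QUAL":
            return [_format_qual(rec)]
        if desc.name == "FILTER":
            if rec.filter_status is None:
                return [MISSING]
            return [normalize(v) for v in rec.filter_status.split(";")]
        raise ConfigurationError(f"unknown core field {desc.name!r}")
    if desc.origin is Origin.INFO:
        raw = rec.info.get(desc.name)
        if raw is None:
            return [MISSING]
        if raw is True:  # flag
            return ["present"]
        return [normalize(v) for v in str(raw).split(",")]
    if desc.origin is Origin.FORMAT:
        fmt_key = desc.name[len("FORMAT_"):] if desc.name.startswith("FORMAT_") else desc.name
        if fmt_key == "GT":
            # keep per-sample GT strings whole; classification parses them
            return [
                normalize(rec.samples.get(s, {}).get("GT")) for s in sample_names
            ]
        values: list[str] = []
        for s in sample_names:
            raw_v = rec.samples.get(s, {}).get(fmt_key)
            if raw_v is None:
                values.append(MISSING)
            else:
                values.extend(normalize(v) for v in raw_v.split(","))
        return values or [MISSING]
    # CSQ sub-field
    if csq_maps is None:
        return [MISSING]
    return [m.get(desc.name, MISSING) for m in csq_maps]


@dataclass
class TableRow:
    chrom: str
    pos: int
    rank: int
    id: str
    ref: str
    alts: tuple[str, ...]
    cells: dict[str, list[str]] = dc_field(default_factory=dict)

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.rank)

    def to_json(self) -> str:
        return json.dumps(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "rank": self.rank,
                "id": self.id,
                "ref": self.ref,
                "alts": list(self.alts),
                "cells": self.cells,
            },
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, line: str) -> "TableRow":
        d = json.loads(line)
        return cls(
            chrom=d["chrom"],
            pos=d["pos"],
            rank=d["rank"],
            id=d["id"],
            ref=d["ref"],
            alts=tuple(d["alts"]),
            cells=d["cells"],
        )


def load_manifest(workdir: str | Path) -> dict:
    path = Path(workdir) / MANIFEST_NAME
    if not path.is_file():
        raise StateError(
            f"no manifest in {workdir}; run the preprocess step first"
        )
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def save_manifest(workdir: str | Path, manifest: dict) -> None:
    """Atomic write: temp file then rename."""
    path = Path(workdir) / MANIFEST_NAME
    tmp = path.with_suffix(".json.tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    os.replace(tmp, path)


class PreprocessedTable:
    """Normalized per-record values of the selected fields, persisted under a
    working directory alongside a JSON manifest (the contract the index and
    filter steps read)."""

    def __init__(
        self,
        workdir: Path,
        source: str,
        fields: list[FieldDescriptor],
        samples: list[str],
        csq_schema: CsqSchema | None,
        rows: list[TableRow],
    ):
        self.workdir = Path(workdir)
        self.source = source
        self.fields = fields
        self.samples = samples
        self.csq_schema = csq_schema
        self.rows = rows
        self._by_rank = {r.rank: r for r in rows}

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def descriptor(self, name: str) -> FieldDescriptor:
        for f in self.fields:
            if f.name == name:
                return f
        raise ConfigurationError(
            f"field {name!r} is not in the table; available: "
            + ", ".join(self.field_names)
        )

    def keys(self) -> list[VariantKey]:
        return [r.key for r in self.rows]

    def row(self, rank: int) -> TableRow:
        return self._by_rank[rank]

    def save(self) -> None:
        self.workdir.mkdir(parents=True, exist_ok=True)
        with open(self.workdir / TABLE_NAME, "w", encoding="utf-8") as fh:
            for r in self.rows:
                fh.write(r.to_json() + "\n")
        try:
            manifest = load_manifest(self.workdir)
        except StateError:
            manifest = {"built": []}
        manifest.update(
            {
                "source": self.source,
                "n_rows": self.n_rows,
                "samples": self.samples,
                "fields": [f.to_dict() for f in self.fields],
                "csq_schema": list(self.csq_schema.subfields) if self.csq_schema else None,
            }
        )
        manifest.setdefault("built", [])
        save_manifest(self.workdir, manifest)

    @classmethod
    def load(cls, workdir: str | Path) -> "PreprocessedTable":
        workdir = Path(workdir)
        manifest = load_manifest(workdir)
        table_path = workdir / TABLE_NAME
        if not table_path.is_file():
            raise StateError(f"no table in {workdir}; run the preprocess step first")
        rows = []
        with open(table_path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(TableRow.from_json(line))
        schema = (
            CsqSchema(tuple(manifest["csq_schema"]))
            if manifest.get("csq_schema")
            else None
        )
        return cls(
            workdir=workdir,
            source=manifest["source"],
            fields=[FieldDescriptor.from_dict(d) for d in manifest["fields"]],
            samples=list(manifest["samples"]),
            csq_schema=schema,
            rows=rows,
        )


def _record_cells(
    rec: VariantRecord,
    descriptors: Iterable[FieldDescriptor],
    samples: Sequence[str],
    schema: CsqSchema | None,
) -> dict[str, list[str]]:
    csq_maps = None
    if schema is not None and any(d.origin is Origin.CSQ for d in descriptors):
        raw = rec.info.get("CSQ")
        if isinstance(raw, str):
            csq_maps = expand_csq(raw, schema, record_label=f"{rec.key.chrom}:{rec.key.pos}")
    return {
        d.name: extract_cell(rec, d, samples, schema, csq_maps) for d in descriptors
    }


def preprocess_vcf(
    path: str | Path, selected: Sequence[str], workdir: str | Path
) -> PreprocessedTable:
    """Single extraction pass over the file for the selected fields.

    Key columns (chrom, pos, rank, id, ref, alts) are always carried; the
    table and its manifest are persisted under ``workdir`` so fields can be
    added incrementally later.
    """
    discovered = {d.name: d for d in discover_fields(path)}
    unknown = [s for s in selected if s not in discovered]
    if unknown:
        raise ConfigurationError(
            f"unknown field(s) {', '.join(unknown)}; valid names: "
            + ", ".join(discovered)
        )
    chosen = [discovered[s] for s in selected]
    with open_vcf(path) as reader:
        subs = reader.header.csq_subfields()
        schema = CsqSchema(tuple(subs)) if subs else None
        samples = list(reader.header.samples)
        rows = []
        for rec in reader:
            rows.append(
                TableRow(
                    chrom=rec.key.chrom,
                    pos=rec.key.pos,
                    rank=rec.key.rank,
                    id=normalize(rec.id),
                    ref=rec.ref,
                    alts=rec.alts,
                    cells=_record_cells(rec, chosen, samples, schema),
                )
            )
    table = PreprocessedTable(
        workdir=Path(workdir),
        source=str(path),
        fields=chosen,
        samples=samples,
        csq_schema=schema,
        rows=rows,
    )
    table.save()
    return table


def extract_additional_field(table: PreprocessedTable, field_name: str) -> FieldDescriptor:
    """Re-pass the source VCF to pull one more field into an existing table.

    Used by the incremental index step; previously extracted cells are left
    untouched.  Returns the new field's descriptor.
    """
    if field_name in table.field_names:
        return table.descriptor(field_name)
    discovered = {d.name: d for d in discover_fields(table.source)}
    if field_name not in discovered:
        raise ConfigurationError(
            f"unknown field {field_name!r}; valid names: " + ", ".join(discovered)
        )
    desc = discovered[field_name]
    with open_vcf(table.source) as reader:
        subs = reader.header.csq_subfields()
        schema = CsqSchema(tuple(subs)) if subs else None
        for rec in reader:
            cells = _record_cells(rec, [desc], table.samples, schema)
            table.row(rec.key.rank).cells[field_name] = cells[field_name]
    table.fields.append(desc)
    table.save()
    return desc
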