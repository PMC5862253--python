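"""Step 2 — per-field index creation.

One compact, queryable index is built per user-chosen field so that filters
never re-scan the source VCF.  An index maps each distinct normalized value
to the ranks of the records carrying it, plus the set of ranks whose values
are *all* missing.  Multi-valued cells contribute one entry per distinct
value but count once in the partition sense: a rank sits in ``missing_ranks``
iff every value of its cell is missing.

Storage is a single sorted plain-text file per field under
``<workdir>/indexes/`` — an embedded, file-backed table needing no server or
administrative privileges.  The serialization is canonical (values sorted,
ranks ascending), so builds are byte-deterministic regardless of how many
worker processes produced them; the manifest's ``built`` list is updated
atomically after each successful build.
"""

from __future__ import annotations

import multiprocessing
import urllib.parse
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .errors import ConfigurationError, StateError
from .preprocess import (
    PreprocessedTable,
    extract_additional_field,
    load_manifest,
    save_manifest,
)
from .vcf_model import MISSING, FieldDescriptor, ValueType

INDEX_DIR = "indexes"


@dataclass
class FieldIndex:
    """In-memory form of one field's index: value -> set of ranks, plus the
    ranks whose cell is entirely missing."""

    field: FieldDescriptor
    entries: dict[str, set[int]] = dc_field(default_factory=dict)
    missing_ranks: set[int] = dc_field(default_factory=set)
    n_rows: int = 0

    def all_ranks(self) -> set[int]:
        out = set(self.missing_ranks)
        for ranks in self.entries.values():
            out |= ranks
        return out


def _tabulate(chunk: list[tuple[int, list[str]]]) -> tuple[dict[str, set[int]], set[int]]:
    entries: dict[str, set[int]] = {}
    missing: set[int] = set()
    for rank, values in chunk:
        non_missing = [v for v in values if v != MISSING]
        if not non_missing:
            missing.add(rank)
            continue
        for v in non_missing:
            entries.setdefault(v, set()).add(rank)
    return entries, missing


def _sort_key_numeric(value: str):
    try:
        return (0, float(value), value)
    except ValueError:
        return (1, 0.0, value)


def build_index(table: PreprocessedTable, field: str, cores: int = 1) -> FieldIndex:
    """Tabulate one field over all rows.

    With ``cores > 1`` the rows are split into contiguous chunks processed by
    a worker pool; the merged result is identical to the serial one —
    parallelism is an implementation detail, determinism is the contract.
    """
    desc = table.descriptor(field)  # ConfigurationError if absent
    rows = [(r.rank, r.cells[field]) for r in table.rows]
    if cores <= 1 or len(rows) < 2:
        parts = [_tabulate(rows)]
    else:
        n_chunks = min(cores, len(rows))
        size = (len(rows) + n_chunks - 1) // n_chunks
        chunks = [rows[i : i + size] for i in range(0, len(rows), size)]
        with multiprocessing.Pool(processes=cores) as pool:
            parts = pool.map(_tabulate, chunks)
    idx = FieldIndex(field=desc, n_rows=len(rows))
    for entries, missing in parts:
        idx.missing_ranks |= missing
        for value, ranks in entries.items():
            idx.entries.setdefault(value, set()).update(ranks)
    return idx


def _serialize(idx: FieldIndex) -> str:
    lines = [
        f"#field={idx.field.name}\ttype={idx.field.value_type.value}\tn_rows={idx.n_rows}"
    ]
    lines.append("M\t" + ",".join(str(r) for r in sorted(idx.missing_ranks)))
    key = _sort_key_numeric if idx.field.is_numeric else (lambda v: v)
    for value in sorted(idx.entries, key=key):
        ranks = ",".join(str(r) for r in sorted(idx.entries[value]))
        lines.append(f"V\t{value}\t{ranks}")
    return "\n".join(lines) + "\n"


def _deserialize(text: str, field: FieldDescriptor) -> FieldIndex:
    lines = text.splitlines()
    header = dict(
        part.split("=", 1) for part in lines[0].lstrip("#").split("\t")
    )
    idx = FieldIndex(field=field, n_rows=int(header["n_rows"]))
    for line in lines[1:]:
        if not line:
            continue
        tag, _, rest = line.partition("\t")
        if tag == "M":
            if rest:
                idx.missing_ranks = {int(r) for r in rest.split(",")}
        else:
            value, _, ranks = rest.partition("\t")
            idx.entries[value] = {int(r) for r in ranks.split(",")} if ranks else set()
    return idx


class IndexStore:
    """Registry of the indexes built under one working directory."""

    def __init__(self, workdir: str | Path):
        self.workdir = Path(workdir)

    def _path_for(self, field: str) -> Path:
        safe = urllib.parse.quote(field, safe="")
        return self.workdir / INDEX_DIR / f"{safe}.idx"

    def built(self) -> list[str]:
        return list(load_manifest(self.workdir).get("built", []))

    def has(self, field: str) -> bool:
        return field in self.built() and self._path_for(field).is_file()

    def build(self, table: PreprocessedTable, field: str, cores: int = 1) -> FieldIndex:
        """Build (or idempotently rebuild) one field's index and persist it."""
        idx = build_index(table, field, cores=cores)
        path = self._path_for(field)
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_suffix(".idx.tmp")
        tmp.write_text(_serialize(idx), encoding="utf-8")
        tmp.replace(path)
        manifest = load_manifest(self.workdir)
        built = manifest.setdefault("built", [])
        if field not in built:
            built.append(field)
        save_manifest(self.workdir, manifest)
        return idx

    def load(self, field: str) -> FieldIndex:
        path = self._path_for(field)
        if not path.is_file():
            raise StateError(
                f"no index for field {field!r}; build it first (step 2)"
            )
        manifest = load_manifest(self.workdir)
        desc = None
        for d in manifest.get("fields", []):
            if d["name"] == field:
                desc = FieldDescriptor.from_dict(d)
                break
        if desc is None:
            raise ConfigurationError(f"field {field!r} missing from the manifest")
        return _deserialize(path.read_text(encoding="utf-8"), desc)


def add_field(
    store: IndexStore, table: PreprocessedTable, field: str, cores: int = 1
) -> IndexStore:
    """Select an additional field at any time.

    If the field is already in the table its index is built when absent and
    the call is otherwise a no-op; a brand-new field triggers a single
    re-pass over the source VCF, then its index build.  Indexes of other
    fields are never touched.
    """
    if field in table.field_names and store.has(field):
        return store
    if field not in table.field_names:
        extract_additional_field(table, field)
    store.build(table, field, cores=cores)
    return store
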