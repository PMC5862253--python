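"""Data model and streaming reader for VCF 4.x files.

The reader handles plain and gzip-compressed files (detected by magic bytes,
not filename), parses the ``##`` meta-section and the ``#CHROM`` column line,
and yields one :class:`VariantRecord` per data line in file order.  Values are
kept as the raw text printed in the file: type interpretation (numeric
comparison, genotype classification) happens downstream, which lets the tool
accept arbitrary annotations, including ones the header never declared.

Duplicate ``(chrom, pos)`` lines are legal — decomposed multi-allelic VCFs
contain them routinely — so every data line additionally carries its ordinal
``rank`` within the file, and ``(chrom, pos, rank)`` is the unique key.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterator

from .errors import (
    GenotypeParseError,
    InputError,
    MalformedRecordError,
    MalformedVcfError,
)

#: Canonical missing-value marker used throughout the package.  Source values
#: "." and "" normalize to this string during pre-processing.
MISSING = "nan"

GZIP_MAGIC = b"\x1f\x8b"


class Origin(str, Enum):
    """Where a filterable field comes from in the VCF."""

    CORE = "CORE"
    INFO = "INFO"
    FORMAT = "FORMAT"
    CSQ = "CSQ"


class ValueType(str, Enum):
    """VCF value types as declared by Type= in the header."""

    INTEGER = "INTEGER"
    FLOAT = "FLOAT"
    STRING = "STRING"
    FLAG = "FLAG"
    CHAR = "CHAR"


@dataclass(frozen=True)
class FieldDescriptor:
    """One discoverable annotation field (core column, INFO key, FORMAT key,
    or VEP CSQ sub-field) with its declared type and arity."""

    name: str
    origin: Origin
    value_type: ValueType = ValueType.STRING
    arity: str = "."
    description: str = ""

    def __post_init__(self) -> None:
        if self.origin is Origin.CSQ and not self.name.startswith("CSQ_"):
            raise ValueError(f"CSQ field name must start with 'CSQ_': {self.name!r}")
        if self.value_type is ValueType.FLAG and self.origin is not Origin.INFO:
            raise ValueError("FLAG-typed fields exist only in INFO")

    @property
    def is_numeric(self) -> bool:
        return self.value_type in (ValueType.INTEGER, ValueType.FLOAT)

    @property
    def is_textual(self) -> bool:
        return self.value_type in (ValueType.STRING, ValueType.CHAR)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "origin": self.origin.value,
            "value_type": self.value_type.value,
            "arity": self.arity,
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldDescriptor":
        return cls(
            name=d["name"],
            origin=Origin(d["origin"]),
            value_type=ValueType(d["value_type"]),
            arity=d.get("arity", "."),
            description=d.get("description", ""),
        )


@dataclass(frozen=True, order=True)
class VariantKey:
    """Unique handle for one data line: chromosome, 1-based position, and the
    line's ordinal rank in the file (disambiguates duplicate positions)."""

    chrom: str
    pos: int
    rank: int


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's parsed GT of arbitrary ploidy.

    ``allele_indices`` holds one integer per allele, ``None`` marking a
    missing allele ("." in the source text).
    """

    allele_indices: tuple[int | None, ...]
    phased: bool
    raw: str


@dataclass
class VariantRecord:
    """One VCF data line: the eight mandatory columns plus, when present,
    FORMAT and per-sample value maps (raw text, keyed by FORMAT key)."""

    key: VariantKey
    id: str | None
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    qual_text: str
    filter_status: str | None
    info: dict[str, str | bool]
    format_keys: tuple[str, ...] = ()
    samples: dict[str, dict[str, str]] = field(default_factory=dict)


@dataclass
class HeaderFieldDef:
    """A ##INFO or ##FORMAT declaration."""

    id: str
    number: str
    type: str
    description: str


_META_RE = re.compile(r"^##(INFO|FORMAT)=<(.*)>\s*$")
_CSQ_FORMAT_RE = re.compile(r"Format:\s*([^\"]+)")


def _split_meta_pairs(body: str) -> dict[str, str]:
    """Split ``ID=CSQ,Number=.,Description="a, b"`` respecting quotes."""
    pairs: dict[str, str] = {}
    key, buf, in_quotes, cur = "", [], False, []
    for ch in body + ",":
        if ch == '"':
            in_quotes = not in_quotes
            continue
        if ch == "," and not in_quotes:
            token = "".join(cur)
            if "=" in token:
                key, _, val = token.partition("=")
                pairs[key.strip()] = val
            cur = []
        else:
            cur.append(ch)
    return pairs


@dataclass
class VcfHeader:
    lines: list[str]
    samples: list[str]
    info_defs: dict[str, HeaderFieldDef]
    format_defs: dict[str, HeaderFieldDef]

    def csq_subfields(self) -> list[str] | None:
        """Sub-field names from the CSQ Description ("Format: A|B|C"), or None
        when no CSQ INFO declaration exists."""
        csq = self.info_defs.get("CSQ")
        if csq is None:
            return None
        m = _CSQ_FORMAT_RE.search(csq.description)
        if m is None:
            return None
        names = [s.strip() for s in m.group(1).split("|") if s.strip()]
        return names or None


class VcfReader:
    """Iterator over the records of one VCF file; parses the header eagerly."""

    def __init__(self, handle: IO[str], source: str):
        self._handle = handle
        self.source = source
        self._line_no = 0
        self.header = self._parse_header()
        self._rank = 0

    def _next_line(self) -> str | None:
        line = self._handle.readline()
        if line == "":
            return None
        self._line_no += 1
        return line

    def _parse_header(self) -> VcfHeader:
        lines: list[str] = []
        info_defs: dict[str, HeaderFieldDef] = {}
        format_defs: dict[str, HeaderFieldDef] = {}
        first = self._next_line()
        if first is None or not first.startswith("##fileformat="):
            raise MalformedVcfError(
                f"{self.source}: not a VCF file (missing ##fileformat= first line)"
            )
        lines.append(first.rstrip("\n"))
        while True:
            line = self._next_line()
            if line is None:
                raise MalformedVcfError(f"{self.source}: no #CHROM column line found")
            if line.startswith("##"):
                lines.append(line.rstrip("\n"))
                m = _META_RE.match(line)
                if m:
                    pairs = _split_meta_pairs(m.group(2))
                    defn = HeaderFieldDef(
                        id=pairs.get("ID", ""),
                        number=pairs.get("Number", "."),
                        type=pairs.get("Type", "String"),
                        description=pairs.get("Description", ""),
                    )
                    if defn.id:
                        target = info_defs if m.group(1) == "INFO" else format_defs
                        target[defn.id] = defn
                continue
            if line.startswith("#CHROM"):
                lines.append(line.rstrip("\n"))
                cols = line.rstrip("\n").split("\t")
                samples = cols[9:] if len(cols) > 9 else []
                return VcfHeader(lines, samples, info_defs, format_defs)
            raise MalformedVcfError(
                f"{self.source}: unexpected line {self._line_no} before #CHROM"
            )

    def __iter__(self) -> Iterator[VariantRecord]:
        return self

    def __next__(self) -> VariantRecord:
        while True:
            line = self._next_line()
            if line is None:
                raise StopIteration
            stripped = line.rstrip("\n")
            if stripped == "":
                continue
            rec = self._parse_record(stripped)
            self._rank += 1
            return rec

    def _parse_record(self, line: str) -> VariantRecord:
        cols = line.split("\t")
        if len(cols) < 8:
            raise MalformedRecordError(
                f"{self.source}: line {self._line_no}: expected >= 8 tab-separated "
                f"columns, found {len(cols)}"
            )
        chrom, pos_s, id_s, ref, alt_s, qual_s, filt_s, info_s = cols[:8]
        try:
            pos = int(pos_s)
        except ValueError:
            raise MalformedRecordError(
                f"{self.source}: line {self._line_no}: POS is not an integer: {pos_s!r}"
            ) from None
        alts = tuple(alt_s.split(",")) if alt_s != "." else ()
        try:
            qual = None if qual_s == "." else float(qual_s)
        except ValueError:
            raise MalformedRecordError(
                f"{self.source}: line {self._line_no}: QUAL is not numeric: {qual_s!r}"
            ) from None
        info: dict[str, str | bool] = {}
        if info_s not in (".", ""):
            for item in info_s.split(";"):
                if not item:
                    continue
                if "=" in item:
                    k, _, v = item.partition("=")
                    info[k] = v
                else:
                    info[item] = True
        format_keys: tuple[str, ...] = ()
        samples: dict[str, dict[str, str]] = {}
        if len(cols) > 8:
            format_keys = tuple(cols[8].split(":"))
            for name, col in zip(self.header.samples, cols[9:]):
                vals = col.split(":")
                samples[name] = dict(zip(format_keys, vals))
        return VariantRecord(
            key=VariantKey(chrom, pos, self._rank),
            id=None if id_s == "." else id_s,
            ref=ref,
            alts=alts,
            qual=qual,
            qual_text=qual_s,
            filter_status=None if filt_s == "." else filt_s,
            info=info,
            format_keys=format_keys,
            samples=samples,
        )

    def close(self) -> None:
        self._handle.close()

    def __enter__(self) -> "VcfReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_vcf(path: str | Path) -> VcfReader:
    """Open a VCF file, transparently decompressing gzip input.

    Compression is detected from the first two bytes (gzip magic), not from
    the filename, so ``.vcf`` files that are secretly gzipped still work.
    """
    p = Path(path)
    if not p.is_file():
        raise InputError(f"no such file: {p}")
    try:
        with open(p, "rb") as fh:
            magic = fh.read(2)
        if magic == GZIP_MAGIC:
            handle: IO[str] = gzip.open(p, "rt", encoding="utf-8")
        else:
            handle = open(p, "rt", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read {p}: {exc}") from exc
    return VcfReader(handle, source=str(p))


_GT_SEP_RE = re.compile(r"[/|]")


def parse_genotype(gt_text: str) -> GenotypeCall:
    """Parse a GT value of arbitrary ploidy.

    Splits on both "/" and "|"; ``phased`` is true iff "|" occurs anywhere.
    Missing allele markers (".") are preserved as ``None``.  The number of
    parsed alleles always equals separator count + 1 — nothing is dropped.
    """
    if not isinstance(gt_text, str) or gt_text == "":
        raise GenotypeParseError(f"empty or non-string GT value: {gt_text!r}")
    indices: list[int | None] = []
    for token in _GT_SEP_RE.split(gt_text):
        if token == ".":
            indices.append(None)
        elif token.isdigit():
            indices.append(int(token))
        else:
            raise GenotypeParseError(f"not GT syntax: {gt_text!r}")
    return GenotypeCall(tuple(indices), phased="|" in gt_text, raw=gt_text)
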