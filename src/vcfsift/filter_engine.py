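"""Step 3 — sequential variant filtering.

Five query types, each a pure per-variant predicate:

1. *field* — compare an annotation field against a cut-off
   (``greater_than`` / ``less_than`` / ``equal_to``, strict inequalities) or
   search it for comma-separated keywords (``contains_keyword``,
   case-insensitive substring, any keyword matching any value keeps the
   record).  The user chooses whether records whose values are all missing
   are kept (``keep_missing``).
2. *genotype* — keep records where the scoped samples carry a genotype class
   (hom-ref / het / hom-alt) under an ALL or ANY quantifier; "one, some or
   all samples" is an explicit sample list plus the quantifier.  A missing
   genotype matches no class.  Classification works at any ploidy and
   ignores phasing.
3. *region* — closed 1-based interval on one chromosome; chromosome names
   match as literal text.
4. *variant type* — SNP / InDel / MNP by REF/ALT length; a record is kept
   when ANY of its alternate alleles classifies as the requested kind.
5. *gene list* — positive (keep associated) or negative (keep the rest)
   query of a symbol-bearing field; association is case-insensitive exact
   token match, values split at "&", "," and ";".

Filters are applied sequentially: each consumes the working set the previous
one produced, so counts never increase along a chain, and the final set of a
chain equals the intersection of the individual answer sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Sequence

from .errors import ConfigurationError
from .field_index import IndexStore
from .preprocess import PreprocessedTable
from .vcf_model import (
    MISSING,
    GenotypeCall,
    VariantKey,
    parse_genotype,
)


class GtClass(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


class VariantKind(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    MNP = "MNP"


class FieldOp(str, Enum):
    GREATER_THAN = "greater_than"
    LESS_THAN = "less_than"
    EQUAL_TO = "equal_to"
    CONTAINS_KEYWORD = "contains_keyword"


class Quantifier(str, Enum):
    ALL = "ALL"
    ANY = "ANY"


class GeneListMode(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


def classify_genotype(call: GenotypeCall) -> GtClass:
    """Genotype class at any ploidy.

    MISSING if any allele index is missing; HOM_REF if all indices are 0;
    HOM_ALT if all indices are equal and non-zero; HET as soon as two
    distinct indices occur.  Allele order (and phasing) never matters.
    """
    idx = call.allele_indices
    if any(i is None for i in idx):
        return GtClass.MISSING
    distinct = set(idx)
    if distinct == {0}:
        return GtClass.HOM_REF
    if len(distinct) == 1:
        return GtClass.HOM_ALT
    return GtClass.HET


_SYMBOLIC_CHARS = set("<>[]")


def classify_variant(ref: str, alt: str) -> VariantKind | None:
    """SNP / MNP / InDel by allele length; symbolic or breakend alternate
    alleles (e.g. "<DEL>", "*") belong to no class and return None."""
    if not alt or alt in (".", "*") or _SYMBOLIC_CHARS & set(alt):
        return None
    if len(ref) == 1 and len(alt) == 1:
        return VariantKind.SNP
    if len(ref) == len(alt):
        return VariantKind.MNP
    return VariantKind.INDEL


@dataclass(frozen=True)
class FieldPredicate:
    field: str
    op: FieldOp
    value: float | str
    keep_missing: bool = False


@dataclass(frozen=True)
class GenotypeQuery:
    gt_class: GtClass
    sample_scope: tuple[str, ...]
    quantifier: Quantifier = Quantifier.ALL


@dataclass
class WorkingSet:
    """Ordered (file-order) set of variant keys surviving the chain so far."""

    keys: tuple[VariantKey, ...]
    origin: str = "all variants"

    @property
    def count(self) -> int:
        return len(self.keys)

    def ranks(self) -> set[int]:
        return {k.rank for k in self.keys}

    @classmethod
    def from_table(cls, table: PreprocessedTable) -> "WorkingSet":
        return cls(tuple(table.keys()))

    def restrict(self, kept_ranks: set[int], origin: str) -> "WorkingSet":
        return WorkingSet(
            tuple(k for k in self.keys if k.rank in kept_ranks), origin=origin
        )


def _parse_float(text: str) -> float | None:
    try:
        return float(text)
    except ValueError:
        return None


def filter_field(ws: WorkingSet, pred: FieldPredicate, store: IndexStore) -> WorkingSet:
    """Field filter answered from the field's index (built in step 2)."""
    idx = store.load(pred.field)  # StateError when not built
    desc = idx.field
    op = FieldOp(pred.op)
    if op in (FieldOp.GREATER_THAN, FieldOp.LESS_THAN) and not desc.is_numeric:
        raise ConfigurationError(
            f"{op.value} needs a numeric field; {desc.name} is {desc.value_type.value}"
        )
    if op is FieldOp.CONTAINS_KEYWORD and not desc.is_textual:
        raise ConfigurationError(
            f"contains_keyword needs a text field; {desc.name} is {desc.value_type.value}"
        )

    matched: set[int] = set()
    if op is FieldOp.CONTAINS_KEYWORD:
        keywords = [k.strip().lower() for k in str(pred.value).split(",") if k.strip()]
        for value, ranks in idx.entries.items():
            low = value.lower()
            if any(kw in low for kw in keywords):
                matched |= ranks
    elif op is FieldOp.EQUAL_TO:
        target_num = _parse_float(str(pred.value))
        for value, ranks in idx.entries.items():
            num = _parse_float(value)
            if target_num is not None and num is not None:
                if num == target_num:
                    matched |= ranks
            elif value == str(pred.value):
                matched |= ranks
    else:
        cutoff = _parse_float(str(pred.value))
        if cutoff is None:
            raise ConfigurationError(
                f"{op.value} cut-off is not numeric: {pred.value!r}"
            )
        for value, ranks in idx.entries.items():
            num = _parse_float(value)
            if num is None:
                continue
            if (op is FieldOp.GREATER_THAN and num > cutoff) or (
                op is FieldOp.LESS_THAN and num < cutoff
            ):
                matched |= ranks
    if pred.keep_missing:
        matched |= idx.missing_ranks
    label = f"field {pred.field} {op.value} {pred.value}"
    return ws.restrict(matched, origin=label)


def genotype_calls(
    table: PreprocessedTable, rank: int, scope: Sequence[str]
) -> dict[str, GenotypeCall | None]:
    """Parsed GT of each scoped sample for one record (None when absent)."""
    row = table.row(rank)
    gt_cell = row.cells["GT"]
    out: dict[str, GenotypeCall | None] = {}
    for sample in scope:
        pos = table.samples.index(sample)
        raw = gt_cell[pos] if pos < len(gt_cell) else MISSING
        out[sample] = None if raw == MISSING else parse_genotype(raw)
    return out


def filter_genotype(
    ws: WorkingSet, query: GenotypeQuery, table: PreprocessedTable
) -> WorkingSet:
    if "GT" not in table.field_names:
        raise ConfigurationError(
            "GT is not among the selected fields; add it before genotype queries"
        )
    if not query.sample_scope:
        raise ConfigurationError("genotype query needs at least one sample")
    unknown = [s for s in query.sample_scope if s not in table.samples]
    if unknown:
        raise ConfigurationError(
            f"unknown sample(s) {', '.join(unknown)}; valid samples: "
            + ", ".join(table.samples)
        )
    want = GtClass(query.gt_class)
    quant = Quantifier(query.quantifier)
    kept: set[int] = set()
    for key in ws.keys:
        calls = genotype_calls(table, key.rank, query.sample_scope)
        matches = [
            call is not None and classify_genotype(call) is want
            for call in calls.values()
        ]
        ok = all(matches) if quant is Quantifier.ALL else any(matches)
        if ok:
            kept.add(key.rank)
    label = f"genotype {want.value} {quant.value} of {list(query.sample_scope)}"
    return ws.restrict(kept, origin=label)


def filter_region(ws: WorkingSet, chrom: str, start: int, end: int) -> WorkingSet:
    """Closed 1-based interval [start, end] on one chromosome."""
    if start > end:
        raise ValueError(f"region start {start} > end {end}")
    kept = {
        k.rank for k in ws.keys if k.chrom == chrom and start <= k.pos <= end
    }
    return ws.restrict(kept, origin=f"region {chrom}:{start}-{end}")


def filter_variant_type(
    ws: WorkingSet, kind: VariantKind, table: PreprocessedTable
) -> WorkingSet:
    want = VariantKind(kind)
    kept: set[int] = set()
    for key in ws.keys:
        row = table.row(key.rank)
        if any(classify_variant(row.ref, alt) is want for alt in row.alts):
            kept.add(key.rank)
    return ws.restrict(kept, origin=f"variant type {want.value}")


_TOKEN_SPLIT_RE = re.compile(r"[&,;]")


def filter_gene_list(
    ws: WorkingSet,
    genes: Sequence[str],
    field: str,
    mode: GeneListMode,
    store: IndexStore,
) -> WorkingSet:
    """Positive/negative gene-symbol query.

    A record is *associated* iff any of its field values contains (as an
    exact token, case-insensitive, values split at "&", "," and ";") any
    listed gene.  POSITIVE keeps associated records; NEGATIVE keeps the
    complement within the working set — records with only missing values are
    not associated, hence kept by NEGATIVE.
    """
    if not genes:
        raise ConfigurationError("gene list must be non-empty")
    idx = store.load(field)
    wanted = {g.strip().casefold() for g in genes if g.strip()}
    associated: set[int] = set()
    for value, ranks in idx.entries.items():
        tokens = {t.strip().casefold() for t in _TOKEN_SPLIT_RE.split(value)}
        if tokens & wanted:
            associated |= ranks
    mode = GeneListMode(mode)
    if mode is GeneListMode.POSITIVE:
        kept = associated
    else:
        kept = ws.ranks() - associated
    label = f"gene list {mode.value} on {field} ({len(wanted)} genes)"
    return ws.restrict(kept, origin=label)


# --- serializable step specifications -------------------------------------
#
# One JSON object per step; the same format is recorded in the filter
# history, so an exported history replays exactly.

def apply_step(
    ws: WorkingSet,
    spec: dict,
    table: PreprocessedTable,
    store: IndexStore,
) -> WorkingSet:
    kind = spec.get("type")
    if kind == "field":
        pred = FieldPredicate(
            field=spec["field"],
            op=FieldOp(spec["op"]),
            value=spec["value"],
            keep_missing=bool(spec.get("keep_missing", False)),
        )
        return filter_field(ws, pred, store)
    if kind == "genotype":
        query = GenotypeQuery(
            gt_class=GtClass(spec["gt_class"]),
            sample_scope=tuple(spec["samples"]),
            quantifier=Quantifier(spec.get("quantifier", "ALL")),
        )
        return filter_genotype(ws, query, table)
    if kind == "region":
        return filter_region(ws, spec["chrom"], int(spec["start"]), int(spec["end"]))
    if kind == "variant_type":
        return filter_variant_type(ws, VariantKind(spec["kind"]), table)
    if kind == "gene_list":
        return filter_gene_list(
            ws,
            spec["genes"],
            spec["field"],
            GeneListMode(spec.get("mode", "POSITIVE")),
            store,
        )
    raise ConfigurationError(f"unknown filter type {kind!r}")


def apply_chain(
    initial: WorkingSet,
    steps: Sequence[dict],
    table: PreprocessedTable,
    store: IndexStore,
    history=None,
):
    """Fold the steps left-to-right, each consuming the previous output.

    Returns ``(final WorkingSet, FilterHistory)``; one history entry is
    recorded per applied filter with its input and output counts.  On error
    the history up to the failing step is preserved (the exception carries
    it no further).
    """
    from .history_export import FilterHistory, FilterStep, utc_now_iso

    if history is None:
        history = FilterHistory(base_count=initial.count)
    ws = initial
    for spec in steps:
        out = apply_step(ws, spec, table, store)
        step = FilterStep(
            ordinal=len(history.steps) + 1,
            filter_type=spec["type"],
            parameters=dict(spec),
            input_count=ws.count,
            output_count=out.count,
            timestamp=utc_now_iso(),
            output_ranks=sorted(out.ranks()),
        )
        history.record_step(step)
        ws = out
    return ws, history
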