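"""Naive re-parse-and-scan oracle, independent of the package under test.

Reads the raw VCF text directly and answers each of the five filter types by
a linear scan, so index-backed answers can be checked against first
principles.  Keys are plain ``(chrom, pos, rank)`` tuples.
"""

from __future__ import annotations

import gzip
import re

MISSING = "nan"


def _open_text(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_vcf(path):
    """Minimal independent VCF scan -> (samples, csq_subfields, rows)."""
    samples: list[str] = []
    csq_subs: list[str] | None = None
    rows = []
    rank = 0
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                m = re.match(r'##INFO=<ID=CSQ,.*Format:\s*([^">]+)', line)
                if m:
                    csq_subs = [s.strip() for s in m.group(1).split("|")]
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:]
                continue
            cols = line.split("\t")
            info = {}
            if cols[7] not in (".", ""):
                for item in cols[7].split(";"):
                    if "=" in item:
                        k, _, v = item.partition("=")
                        info[k] = v
                    elif item:
                        info[item] = True
            fmt = cols[8].split(":") if len(cols) > 8 else []
            svals = []
            for col in cols[9:]:
                svals.append(dict(zip(fmt, col.split(":"))))
            rows.append(
                {
                    "chrom": cols[0],
                    "pos": int(cols[1]),
                    "rank": rank,
                    "id": cols[2],
                    "ref": cols[3],
                    "alts": cols[4].split(",") if cols[4] != "." else [],
                    "qual": cols[5],
                    "filter": cols[6],
                    "info": info,
                    "samples": svals,
                }
            )
            rank += 1
    return samples, csq_subs, rows


def _norm(v):
    return MISSING if v is None or v in (".", "") else v


def field_values(row, field, samples, csq_subs):
    """Normalized value list of one field for one row (the same semantics the
    package documents, derived here straight from the raw line)."""
    if field == "CHROM+POS":
        return [f"{row['chrom']}:{row['pos']}"]
    if field == "ID":
        return [_norm(row["id"])]
    if field == "REF+ALT":
        if not row["alts"]:
            return [MISSING]
        return [f"{row['ref']}>{a}" for a in row["alts"]]
    if field == "QUAL":
        return [_norm(row["qual"])]
    if field == "FILTER":
        if row["filter"] == ".":
            return [MISSING]
        return [_norm(p) for p in row["filter"].split(";")]
    if field.startswith("CSQ_") and csq_subs:
        raw = row["info"].get("CSQ")
        if not isinstance(raw, str):
            return [MISSING]
        pos = csq_subs.index(field[4:])
        out = []
        for block in raw.split(","):
            parts = block.split("|")
            out.append(_norm(parts[pos]) if pos < len(parts) else MISSING)
        return out
    if field == "GT" or field.startswith("FORMAT_") and field[7:] == "GT":
        return [_norm(sv.get("GT")) for sv in row["samples"]]
    if field in row["info"] or any(field in sv for sv in row["samples"]):
        if field in row["info"]:
            raw = row["info"][field]
            if raw is True:
                return ["present"]
            return [_norm(v) for v in str(raw).split(",")]
        out = []
        for sv in row["samples"]:
            raw = sv.get(field)
            if raw is None:
                out.append(MISSING)
            else:
                out.extend(_norm(v) for v in raw.split(","))
        return out
    # FORMAT_-prefixed or absent everywhere
    key = field[7:] if field.startswith("FORMAT_") else field
    out = []
    for sv in row["samples"]:
        raw = sv.get(key)
        if raw is None:
            out.append(MISSING)
        else:
            out.extend(_norm(v) for v in raw.split(","))
    return out or [MISSING]


def _key(row):
    return (row["chrom"], row["pos"], row["rank"])


def _float(v):
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def oracle_field(rows, samples, csq_subs, field, op, value, keep_missing):
    kept = set()
    for row in rows:
        vals = field_values(row, field, samples, csq_subs)
        non_missing = [v for v in vals if v != MISSING]
        if not non_missing:
            if keep_missing:
                kept.add(_key(row))
            continue
        if op == "contains_keyword":
            kws = [k.strip().lower() for k in str(value).split(",") if k.strip()]
            hit = any(kw in v.lower() for v in non_missing for kw in kws)
        elif op == "equal_to":
            tnum = _float(value)
            hit = False
            for v in non_missing:
                num = _float(v)
                if tnum is not None and num is not None:
                    hit = hit or num == tnum
                else:
                    hit = hit or v == str(value)
        else:
            cutoff = float(value)
            nums = [n for n in (_float(v) for v in non_missing) if n is not None]
            if op == "greater_than":
                hit = any(n > cutoff for n in nums)
            else:
                hit = any(n < cutoff for n in nums)
        if hit:
            kept.add(_key(row))
    return kept


def gt_class(gt_text):
    if gt_text in (None, ".", ""):
        return "MISSING"
    tokens = re.split(r"[/|]", gt_text)
    idx = []
    for t in tokens:
        if t == ".":
            return "MISSING"
        idx.append(int(t))
    if set(idx) == {0}:
        return "HOM_REF"
    if len(set(idx)) == 1:
        return "HOM_ALT"
    return "HET"


def oracle_genotype(rows, samples, scope, wanted, quantifier):
    kept = set()
    positions = [samples.index(s) for s in scope]
    for row in rows:
        matches = [
            gt_class(row["samples"][p].get("GT")) == wanted for p in positions
        ]
        ok = all(matches) if quantifier == "ALL" else any(matches)
        if ok:
            kept.add(_key(row))
    return kept


def oracle_region(rows, chrom, start, end):
    return {
        _key(r) for r in rows if r["chrom"] == chrom and start <= r["pos"] <= end
    }


def variant_kind(ref, alt):
    if not alt or alt in (".", "*") or any(c in alt for c in "<>[]"):
        return None
    if len(ref) == 1 == len(alt):
        return "SNP"
    if len(ref) == len(alt):
        return "MNP"
    return "INDEL"


def oracle_variant_type(rows, kind):
    return {
        _key(r)
        for r in rows
        if any(variant_kind(r["ref"], a) == kind for a in r["alts"])
    }


def oracle_gene_list(rows, samples, csq_subs, genes, field, mode):
    wanted = {g.strip().casefold() for g in genes}
    associated = set()
    for row in rows:
        vals = [v for v in field_values(row, field, samples, csq_subs) if v != MISSING]
        tokens = {
            t.strip().casefold() for v in vals for t in re.split(r"[&,;]", v)
        }
        if tokens & wanted:
            associated.add(_key(row))
    if mode == "POSITIVE":
        return associated
    return {_key(r) for r in rows} - associated
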