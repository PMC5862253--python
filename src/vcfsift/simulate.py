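"""Deterministic synthetic-VCF generator.

Produces standards-conformant VCF 4.2 files (plain or gzip) with arbitrary
samples, ploidies, INFO annotations and VEP-style CSQ strings, together with
a ground-truth sidecar (per-variant true type per alternate allele, true
genotype class per sample, true annotation values) that oracle tests read
instead of re-deriving expectations from the code under test.  The same seed
always yields byte-identical output.

Presets embed the two study designs the genotype filter exists for: a
mother/father/child trio with a chosen number of de novo rows (parents
hom-ref, child het; every other row is constructed NOT to match that
pattern) and a tumour/normal pair with a chosen number of rows where the
normal sample is hom-ref.

Structural realism only: no population-genetic model, no linkage.
Chromosome naming mixes bare ("1") and prefixed ("chr1") styles across
presets because the filters match chromosome names as literal text.
"""

from __future__ import annotations

import gzip as gzip_mod
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path

CONSEQUENCES = [
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "frameshift_variant",
    "stop_gained",
    "stop_lost",
    "5_prime_UTR_variant",
    "splice_region_variant",
]

GENES = ["BRCA2", "TP53", "EGFR", "BRCA1", "BRCA1P1", "MLH1", "KRAS", "PTEN"]

BASES = "ACGT"

#: (name, VCF Type, Number, missing_rate)
DEFAULT_INFO_FIELDS: tuple[tuple[str, str, str, float], ...] = (
    ("AF", "Float", "A", 0.3),
    ("DP", "Integer", "1", 0.1),
    ("DB", "Flag", "0", 0.7),
)


@dataclass
class FixtureSpec:
    """Everything needed to generate one reproducible fixture."""

    n_variants: int
    samples: tuple[str, ...] = ("sample1",)
    ploidy: int | dict[str, int] = 2
    info_fields: tuple[tuple[str, str, str, float], ...] = DEFAULT_INFO_FIELDS
    with_csq: bool = True
    csq_subfields: tuple[str, ...] = ("Allele", "Consequence", "SYMBOL")
    variant_type_mix: dict[str, float] = dc_field(
        default_factory=lambda: {"SNP": 0.7, "INDEL": 0.2, "MNP": 0.1}
    )
    multiallelic_rate: float = 0.1
    duplicate_pos_rate: float = 0.02
    qual_missing_rate: float = 0.1
    gt_missing_rate: float = 0.1
    chroms: tuple[str, ...] = ("1", "2", "X")
    gzip: bool = False
    seed: int = 0
    scenario: dict | None = None

    def validate(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")
        total = sum(self.variant_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant_type_mix must sum to 1, got {total}")
        for rate in (
            self.multiallelic_rate,
            self.duplicate_pos_rate,
            self.qual_missing_rate,
            self.gt_missing_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate out of [0,1]: {rate}")
        for _, _, _, mr in self.info_fields:
            if not 0.0 <= mr <= 1.0:
                raise ValueError(f"missing_rate out of [0,1]: {mr}")
        if not self.samples and self.scenario:
            raise ValueError("scenario presets need samples")

    def sample_ploidy(self, sample: str) -> int:
        if isinstance(self.ploidy, dict):
            return self.ploidy.get(sample, 2)
        return self.ploidy


def _pick_kind(rng: random.Random, mix: dict[str, float]) -> str:
    x = rng.random()
    acc = 0.0
    for kind in ("SNP", "INDEL", "MNP"):  # fixed order for determinism
        acc += mix.get(kind, 0.0)
        if x < acc:
            return kind
    return "SNP"


def _alleles(rng: random.Random, kind: str) -> tuple[str, str]:
    """REF and one ALT of the requested true kind."""
    if kind == "SNP":
        ref = rng.choice(BASES)
        alt = rng.choice([b for b in BASES if b != ref])
        return ref, alt
    if kind == "MNP":
        n = rng.randint(2, 3)
        ref = "".join(rng.choice(BASES) for _ in range(n))
        while True:
            alt = "".join(rng.choice(BASES) for _ in range(n))
            if alt != ref:
                return ref, alt
    # INDEL: insertion or deletion
    if rng.random() < 0.5:
        ref = rng.choice(BASES)
        ins = "".join(rng.choice(BASES) for _ in range(rng.randint(1, 3)))
        return ref, ref + ins
    n = rng.randint(2, 4)
    ref = "".join(rng.choice(BASES) for _ in range(n))
    return ref, ref[0]


def _genotype_class(indices: list[int | None]) -> str:
    # truth-by-construction classifier, local to the generator
    if any(i is None for i in indices):
        return "MISSING"
    distinct = set(indices)
    if distinct == {0}:
        return "HOM_REF"
    if len(distinct) == 1:
        return "HOM_ALT"
    return "HET"


def _gt_string(rng: random.Random, indices: list[int | None]) -> str:
    sep = "|" if rng.random() < 0.2 and len(indices) > 1 else "/"
    return sep.join("." if i is None else str(i) for i in indices)


def _draw_genotype(
    rng: random.Random, ploidy: int, n_alts: int, missing_rate: float
) -> list[int | None]:
    if rng.random() < missing_rate:
        return [None] * ploidy
    return [rng.randint(0, n_alts) for _ in range(ploidy)]


def _scenario_genotypes(
    spec: FixtureSpec, rng: random.Random, rank: int, n_alts: int
) -> dict[str, list[int | None]] | None:
    """Constructed genotypes for scenario fixtures; None → draw freely."""
    sc = spec.scenario
    if not sc:
        return None
    designated = rank in set(sc["ranks"])
    if sc["kind"] == "trio_denovo":
        mother, father, child = spec.samples
        if designated:
            return {mother: [0, 0], father: [0, 0], child: [0, 1]}
        gts = {
            s: _draw_genotype(rng, spec.sample_ploidy(s), n_alts, spec.gt_missing_rate)
            for s in spec.samples
        }
        # forbid the de novo pattern off the designated rows
        parents_ref = all(
            _genotype_class(gts[s]) == "HOM_REF" for s in (mother, father)
        )
        if parents_ref and _genotype_class(gts[child]) == "HET":
            gts[child] = [0, 0] if rng.random() < 0.5 else [1, 1]
        return gts
    if sc["kind"] == "tumour_normal":
        normal, tumour = spec.samples
        if designated:
            tum = [0, 1] if rng.random() < 0.5 else [1, 1]
            return {normal: [0, 0], tumour: tum}
        # normal must NOT be hom-ref off the designated rows
        choices = [[0, 1], [1, 1], [None, None]]
        return {
            normal: list(rng.choice(choices)),
            tumour: _draw_genotype(rng, 2, n_alts, spec.gt_missing_rate),
        }
    raise ValueError(f"unknown scenario kind {sc['kind']!r}")


def _info_value(
    rng: random.Random, vtype: str, number: str, n_alts: int
) -> str:
    def one() -> str:
        if vtype == "Integer":
            return str(rng.randint(0, 200))
        if vtype == "Float":
            return str(round(10 ** rng.uniform(-4, 0), 4))
        if vtype == "Character":
            return rng.choice("ACGTN")
        return rng.choice(["benign", "pathogenic", "uncertain", "protective"])

    if number == "A":
        return ",".join(one() for _ in range(n_alts))
    if number == ".":
        return ",".join(one() for _ in range(rng.randint(1, 3)))
    return one()


def _header_lines(spec: FixtureSpec) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=vcfsift-simulate"]
    for chrom in spec.chroms:
        lines.append(f"##contig=<ID={chrom}>")
    for name, vtype, number, _ in spec.info_fields:
        lines.append(
            f'##INFO=<ID={name},Number={number},Type={vtype},Description="simulated {name}">'
        )
    if spec.with_csq:
        fmt = "|".join(spec.csq_subfields)
        lines.append(
            f'##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations '
            f'from Ensembl VEP. Format: {fmt}">'
        )
    if spec.samples:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if spec.samples:
        cols += ["FORMAT"] + list(spec.samples)
    lines.append("\t".join(cols))
    return lines


def generate_vcf(spec: FixtureSpec, path: str | Path) -> tuple[Path, Path]:
    """Write the fixture VCF and its ground-truth sidecar.

    Returns ``(vcf_path, truth_path)``.  The sidecar is a TSV holding, per
    data line: position key, alleles, the true kind of each alternate
    allele, QUAL/FILTER as written, each INFO field's true value, the true
    genotype class of every sample, and the CSQ consequence/symbol sets.
    Same seed, same bytes — gzip output uses a fixed mtime.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    path = Path(path)

    truth_cols = ["chrom", "pos", "rank", "ref", "alts", "kinds", "qual", "filter"]
    truth_cols += [f"info:{name}" for name, *_ in spec.info_fields]
    truth_cols += [f"gt_class:{s}" for s in spec.samples]
    if spec.with_csq:
        truth_cols += ["csq_consequences", "csq_symbols"]

    body: list[str] = []
    truth: list[str] = []
    per_chrom = max(1, (spec.n_variants + len(spec.chroms) - 1) // len(spec.chroms))
    pos_by_chrom = {c: 0 for c in spec.chroms}
    prev: tuple[str, int] | None = None

    for rank in range(spec.n_variants):
        chrom = spec.chroms[min(rank // per_chrom, len(spec.chroms) - 1)]
        if prev is not None and prev[0] == chrom and rng.random() < spec.duplicate_pos_rate:
            pos = prev[1]
        else:
            pos_by_chrom[chrom] += rng.randint(1, 1000)
            pos = pos_by_chrom[chrom]
        pos_by_chrom[chrom] = max(pos_by_chrom[chrom], pos)
        prev = (chrom, pos)

        kinds = [_pick_kind(rng, spec.variant_type_mix)]
        ref, alt = _alleles(rng, kinds[0])
        alts = [alt]
        if rng.random() < spec.multiallelic_rate:
            kind2 = _pick_kind(rng, spec.variant_type_mix)
            # second allele must share REF: regenerate until compatible
            for _ in range(50):
                r2, a2 = _alleles(rng, kind2)
                if kind2 == "SNP" and len(ref) == 1:
                    a2 = rng.choice([b for b in BASES if b not in (ref, alts[0])])
                    break
                if kind2 == "INDEL":
                    a2 = ref + "".join(
                        rng.choice(BASES) for _ in range(rng.randint(1, 3))
                    )
                    break
                if kind2 == "MNP" and len(ref) > 1:
                    a2 = "".join(rng.choice(BASES) for _ in range(len(ref)))
                    if a2 != ref and a2 not in alts:
                        break
            else:
                a2 = None
            if a2 and a2 not in alts and a2 != ref:
                actual = (
                    "SNP"
                    if len(ref) == 1 and len(a2) == 1
                    else ("MNP" if len(ref) == len(a2) else "INDEL")
                )
                alts.append(a2)
                kinds.append(actual)
        n_alts = len(alts)

        vid = f"rs{rng.randint(10**6, 10**8)}" if rng.random() < 0.3 else "."
        qual = "." if rng.random() < spec.qual_missing_rate else str(
            round(rng.uniform(0, 100), 1)
        )
        filt = "PASS" if rng.random() < 0.7 else rng.choice(["q10", "s50", "q10;s50"])

        info_parts: list[str] = []
        info_truth: list[str] = []
        for name, vtype, number, missing_rate in spec.info_fields:
            if vtype == "Flag":
                present = rng.random() >= missing_rate
                if present:
                    info_parts.append(name)
                info_truth.append("present" if present else "nan")
                continue
            if rng.random() < missing_rate:
                info_parts.append(f"{name}=.")
                info_truth.append("nan")
            else:
                val = _info_value(rng, vtype, number, n_alts)
                info_parts.append(f"{name}={val}")
                info_truth.append(val.replace(",", "|"))

        csq_cons: list[str] = []
        csq_syms: list[str] = []
        if spec.with_csq:
            blocks = []
            for _ in range(rng.randint(1, 4)):
                sub: list[str] = []
                for name in spec.csq_subfields:
                    if name == "Allele":
                        sub.append(alts[0])
                    elif name == "Consequence":
                        term = "" if rng.random() < 0.1 else rng.choice(CONSEQUENCES)
                        sub.append(term)
                        csq_cons.append(term if term else "nan")
                    elif name == "SYMBOL":
                        sym = "" if rng.random() < 0.1 else rng.choice(GENES)
                        sub.append(sym)
                        csq_syms.append(sym if sym else "nan")
                    else:
                        sub.append("" if rng.random() < 0.3 else f"x{rng.randint(1,99)}")
                blocks.append("|".join(sub))
            info_parts.append("CSQ=" + ",".join(blocks))

        gt_classes: list[str] = []
        sample_cols: list[str] = []
        fixed = _scenario_genotypes(spec, rng, rank, n_alts)
        for s in spec.samples:
            if fixed is not None:
                indices = fixed[s]
            else:
                indices = _draw_genotype(
                    rng, spec.sample_ploidy(s), n_alts, spec.gt_missing_rate
                )
            gt_classes.append(_genotype_class(indices))
            dp = rng.randint(0, 150)
            sample_cols.append(f"{_gt_string(rng, indices)}:{dp}")

        cols = [chrom, str(pos), vid, ref, ",".join(alts), qual, filt,
                ";".join(info_parts) if info_parts else "."]
        if spec.samples:
            cols += ["GT:DP"] + sample_cols
        body.append("\t".join(cols))

        trow = [chrom, str(pos), str(rank), ref, ",".join(alts),
                "|".join(kinds), qual if qual != "." else "nan",
                filt]
        trow += info_truth
        trow += gt_classes
        if spec.with_csq:
            trow.append("|".join(csq_cons))
            trow.append("|".join(csq_syms))
        truth.append("\t".join(trow))

    text = "\n".join(_header_lines(spec) + body) + "\n"
    if spec.gzip:
        path.write_bytes(gzip_mod.compress(text.encode("utf-8"), mtime=0))
    else:
        path.write_text(text, encoding="utf-8")

    truth_path = Path(str(path) + ".truth.tsv")
    truth_path.write_text(
        "\t".join(truth_cols) + "\n" + "\n".join(truth) + ("\n" if truth else ""),
        encoding="utf-8",
    )
    return path, truth_path


def load_truth(truth_path: str | Path) -> list[dict[str, str]]:
    """Read a ground-truth sidecar back as one dict per data line."""
    lines = Path(truth_path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:] if line]


def trio_preset(n_variants: int, n_denovo: int, seed: int) -> FixtureSpec:
    """Mother/father/child joint-calling fixture with exactly ``n_denovo``
    rows carrying the de novo pattern (parents 0/0, child 0/1)."""
    if n_denovo > n_variants:
        raise ValueError("n_denovo cannot exceed n_variants")
    ranks = sorted(random.Random(seed).sample(range(n_variants), n_denovo))
    return FixtureSpec(
        n_variants=n_variants,
        samples=("mother", "father", "child"),
        chroms=("chr1", "chr2"),
        seed=seed,
        scenario={"kind": "trio_denovo", "ranks": ranks},
    )


def tumour_normal_preset(n_variants: int, n_hom_ref_normal: int, seed: int) -> FixtureSpec:
    """Matched tumour/normal pair with exactly ``n_hom_ref_normal`` rows
    where the normal sample is hom-ref (somatic candidates under joint
    calling)."""
    if n_hom_ref_normal > n_variants:
        raise ValueError("n_hom_ref_normal cannot exceed n_variants")
    ranks = sorted(random.Random(seed).sample(range(n_variants), n_hom_ref_normal))
    return FixtureSpec(
        n_variants=n_variants,
        samples=("normal", "tumour"),
        chroms=("chr1", "chr2"),
        seed=seed,
        scenario={"kind": "tumour_normal", "ranks": ranks},
    )
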