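import gzip
from pathlib import Path

import pytest

from vcfsift import (
    IndexStore,
    PreprocessedTable,
    WorkingSet,
    preprocess_vcf,
)
from vcfsift.field_index import add_field

# Five records chosen to exercise every corner at once: QUAL column
# {10, ., 50, 30, 100}; two lines sharing (chrom 1, pos 100); an INFO key
# (UNDECLARED) used in the body but absent from the header; a multi-allelic
# record mixing SNP and InDel alternates; a haploid child GT; a symbolic
# <DEL> alternate; multi-transcript CSQ strings with empty sub-values; a
# trio whose only de novo row (parents 0/0, child 0/1) is rank 0.
HAND_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">
##INFO=<ID=CSQ,Number=.,Type=String,Description="VEP. Format: Allele|Consequence|SYMBOL">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmother\tfather\tchild
1\t100\t.\tA\tG\t10\tPASS\tAF=0.5;DP=10;DB;CSQ=G|missense_variant|BRCA2\tGT\t0/0\t0/0\t0/1
1\t100\trs1\tAT\tA\t.\tq10\tAF=0.001;CSQ=-|frameshift_variant|BRCA2,-|intron_variant|BRCA2\tGT\t0/1\t0/0\t1|1
1\t200\t.\tAT\tGC\t50\tPASS\tDP=20;UNDECLARED=7;CSQ=GC||TP53\tGT\t./.\t0/1\t0/1
2\t50\t.\tC\tT,CTT\t30\tPASS\tAF=0.2,0.01;CSQ=T|stop_gained|EGFR,CTT|intron_variant|\tGT\t1/2\t0/0\t2
2\t300\t.\tG\t<DEL>\t100\tq10;s50\tAF=.\tGT\t0/0\t1/1\t0/0
"""

HAND_FIELDS = ["QUAL", "FILTER", "AF", "DP", "GT", "CSQ_Consequence", "CSQ_SYMBOL"]


@pytest.fixture()
def hand_vcf(tmp_path: Path) -> Path:
    path = tmp_path / "hand.vcf"
    path.write_text(HAND_VCF, encoding="utf-8")
    return path


@pytest.fixture()
def hand_vcf_gz(tmp_path: Path) -> Path:
    path = tmp_path / "hand.vcf.gz"
    path.write_bytes(gzip.compress(HAND_VCF.encode("utf-8"), mtime=0))
    return path


def build_workspace(vcf_path, workdir, fields=None, index_fields=None):
    """Preprocess + index helper shared across tests; returns (table, store)."""
    fields = HAND_FIELDS if fields is None else fields
    table = preprocess_vcf(vcf_path, fields, workdir)
    store = IndexStore(workdir)
    for f in index_fields if index_fields is not None else fields:
        if f in table.field_names:
            store.build(table, f)
        else:
            add_field(store, table, f)
    return table, store


@pytest.fixture()
def hand_workspace(hand_vcf, tmp_path):
    table, store = build_workspace(hand_vcf, tmp_path / "wd")
    return table, store


@pytest.fixture()
def hand_ws(hand_workspace):
    table, _ = hand_workspace
    return WorkingSet.from_table(table)
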