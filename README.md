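# vcfsift

Sequential variant prioritization for annotated VCF files.

After variant calling and annotation, a sequencing experiment leaves a VCF
with millions of candidate lines and dozens of annotation fields — INFO
key/value pairs, flags, per-sample FORMAT values, and (when the file was
annotated with Ensembl VEP) long pipe-delimited `CSQ` strings packing many
sub-fields per transcript. Narrowing those lines down to a handful of
candidate disease alleles means applying a *sequence* of filters — quality,
population allele frequency, genotype pattern in a family or tumour/normal
pair, consequence keywords, gene lists, regions — where each filter operates
on the survivors of the previous one. `vcfsift` does exactly that, for
researchers and pipelines that need the filtering step to be reproducible:
every applied filter is written to a replayable history, and the surviving
variants export as a spreadsheet-ready TSV.

The workflow has three steps:

1. **Pre-process** — discover every filterable field in the input (the five
   core column groups `CHROM+POS`, `ID`, `REF+ALT`, `QUAL`, `FILTER`; every
   INFO and FORMAT key, declared in the header or merely observed in the
   body; and one `CSQ_<subfield>` per VEP sub-field), normalize missing
   values (`.` and empty become `nan`), and persist the user-selected
   columns under a working directory. Plain and gzip-compressed input are
   both accepted; compression is detected from the file's bytes, not its
   name.
2. **Index** — build one compact per-field index (distinct value → record
   set) so queries never re-scan the VCF. Fields can be added at any time;
   multi-core builds produce byte-identical artifacts.
3. **Filter** — apply any sequence of the five query types:
   * **field**: `greater_than` / `less_than` / `equal_to` a cut-off
     (strict inequalities), or `contains_keyword` with a comma-separated
     keyword list (case-insensitive substring; any keyword hitting any value
     keeps the record), with an include/exclude switch for records whose
     values are all missing;
   * **genotype**: hom-ref / het / hom-alt in one, some or all of the named
     samples (ALL/ANY quantifier), at any ploidy, phasing ignored —
     a genotype is hom-ref when every allele index is 0, hom-alt when all
     indices are equal and non-zero, het as soon as two distinct indices
     occur, and a missing genotype matches no class;
   * **region**: closed 1-based interval on one chromosome;
   * **variant type**: SNP (len(REF)=len(ALT)=1), MNP (equal lengths > 1)
     or InDel (unequal lengths), any-match over alternate alleles;
   * **gene list**: positive or negative query of a symbol-bearing field,
     case-insensitive exact-token match.

A deterministic fixture generator (`vcfsift simulate` /
`vcfsift.simulate`) produces structurally realistic annotated VCFs with a
ground-truth sidecar, including trio and tumour/normal presets, so the whole
workflow is testable without any external dataset.

## Worked example: de novo candidates in a trio

Simulate a 200-variant mother/father/child joint-called VCF with five
embedded de novo rows, then run the classic chain — parents homozygous
reference, child heterozygous, then keep rare-or-unobserved alleles:

```sh
$ vcfsift simulate --out toy.vcf --n 200 --seed 7 --preset trio --designated 5
toy.vcf + toy.vcf.truth.tsv
$ vcfsift preprocess toy.vcf --workdir wd --fields QUAL,FILTER,AF,GT,CSQ_Consequence
200 variants, 5 fields -> wd
$ vcfsift index --workdir wd --field AF
indexed AF
$ vcfsift query genotype --workdir wd --gt-class HOM_REF --samples mother,father --quantifier ALL
11 variants
$ vcfsift query genotype --workdir wd --gt-class HET --samples child
5 variants
$ vcfsift query field --workdir wd --field AF --op less_than --value 0.01 --keep-missing
5 variants
$ vcfsift history --workdir wd
base: 200 variants
1. genotype {'type': 'genotype', 'gt_class': 'HOM_REF', 'samples': ['mother', 'father'], 'quantifier': 'ALL'} 200 -> 11
2. genotype {'type': 'genotype', 'gt_class': 'HET', 'samples': ['child'], 'quantifier': 'ALL'} 11 -> 5
3. field {'type': 'field', 'field': 'AF', 'op': 'less_than', 'value': '0.01', 'keep_missing': True} 5 -> 5
$ vcfsift export --workdir wd --out candidates.tsv
5 variants -> candidates.tsv
```

Reading the numbers: 11 of the 200 records have both parents called `0/0`;
5 of those have a heterozygous child — exactly the 5 rows the simulator
designated de novo, with no false positives; the allele-frequency step keeps
all 5 because each is either rare (AF < 0.01) or absent from the simulated
frequency database (`--keep-missing`). The exported `candidates.tsv` has one
header line plus 5 data rows and opens directly in a spreadsheet.

The same operations are available as a library:

```python
from vcfsift import WorkingSet, apply_chain, preprocess_vcf
from vcfsift.field_index import IndexStore

table = preprocess_vcf("toy.vcf", ["AF", "GT"], "wd")
store = IndexStore("wd"); store.build(table, "AF")
final, history = apply_chain(
    WorkingSet.from_table(table),
    [{"type": "genotype", "gt_class": "HOM_REF",
      "samples": ["mother", "father"], "quantifier": "ALL"},
     {"type": "genotype", "gt_class": "HET", "samples": ["child"],
      "quantifier": "ALL"}],
    table, store)
print(final.count)  # 5
```

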