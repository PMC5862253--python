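# Methods

## Data model

A VCF data line is identified by `(chrom, pos, rank)`: chromosome name as
literal text, the 1-based position exactly as printed, and the line's
ordinal within the file. The rank exists because decomposed multi-allelic
VCFs legally contain several lines at the same `(chrom, pos)`; it also makes
every working set's file order well defined. Coordinates are never shifted:
region queries use the closed 1-based interval `[start, end]`, matching the
convention users see in the `POS` column. Chromosome names are compared as
exact strings — no `chr` prefix normalization — because silently equating
naming styles is how variants from the wrong assembly slip through; the
fixture generator deliberately mixes both styles across presets so tests
exercise this.

All values are carried as the raw text printed in the file. The canonical
missing marker is the string `nan`; the source markers `.` and the empty
string (frequent inside VEP sub-fields) normalize to it during
pre-processing, and numeric comparisons treat it as missing, never as a
number. INFO flags become `present`/missing.

Cells are value *lists*, not scalars: a multi-valued INFO field (arity A, R,
G or `.`) keeps all its values; a FORMAT field holds one slot per sample
(with `GT` kept whole and per-sample — it is the one FORMAT value whose
internal structure matters); a CSQ sub-field holds one value per transcript
block. Filters use any-match over these lists, and a cell counts as missing
only when every one of its values is missing. Any-match is the recall-
preserving choice for a prioritization tool: a variant whose third
transcript is `missense_variant` should survive a missense query. A record
is always kept or dropped whole; there is no allele splitting.

## Field discovery and CSQ expansion

Discovery returns the union of five core composite fields (`CHROM+POS`,
`ID`, `REF+ALT`, `QUAL`, `FILTER` — grouped the way the indexes are built),
every INFO key and every FORMAT key that is either declared in the header or
merely observed in the body, and the VEP sub-fields. Undeclared-but-observed
keys are typed STRING with arity `.` — real-world VCFs carry in-house
annotations that never made it into the header, and refusing them would
defeat the point of an annotation-agnostic filter. When an INFO key and a
FORMAT key collide (the classic `DP`), the FORMAT side is exposed as
`FORMAT_<key>` so that names stay unique.

The `CSQ` INFO value packs one pipe-delimited block per transcript, blocks
separated by commas, sub-field order declared after `Format:` in the CSQ
header line. Expansion replaces the bare `CSQ` key with one `CSQ_<name>`
field per sub-field; blocks shorter than the schema are right-padded with
missing (VEP truncates trailing empties), blocks longer than the schema are
a hard error naming the record, since they mean the file and its header
disagree. Only `CSQ` receives this treatment; SnpEff `ANN` strings pass
through as ordinary INFO text.

## Indexes

One index per chosen field: a map from each distinct normalized value to the
set of ranks carrying it, plus the set of ranks whose cell is entirely
missing. These two parts partition the table's key set. Storage is one
sorted plain-text file per field under `workdir/indexes/` — an embedded,
file-backed store requiring no server or privileges. The serialization is
canonical (missing line first, values sorted — numerically for
INTEGER/FLOAT fields, lexicographically otherwise — ranks ascending), which
makes builds byte-deterministic by construction: with `cores > 1` the rows
are split into contiguous chunks for a process pool and the merged result is
identical to the serial one. Numeric fields are compared as floats at query
time, so `30` matches `30.0` regardless of how the file printed it; VCF
headers mistype `Number`/`Type` often enough that trusting the text form
would be wrong.

The manifest (`workdir/manifest.json`) records the source path, selected
fields, row count, sample names, CSQ schema and the list of built indexes;
it is rewritten atomically (temp file + rename) after every successful
build, and is the contract every later step reads. Adding a field later
costs one re-pass over the source VCF and touches no existing index file.

## Filter semantics

* `greater_than` / `less_than` are strict; the canonical rare-variant query
  is "AF **<** 0.01", which reads as strict.
* `equal_to` compares numerically when both sides parse as numbers and as
  exact strings otherwise (so `FILTER equal_to PASS` works); multi-token
  FILTER values (`q10;s50`) are split at `;` and any token may match.
* `contains_keyword` splits the query at commas and keeps a record if any
  keyword is a case-insensitive substring of any value — compound
  consequence terms (`missense_variant`) must match the keyword `missense`.
* Gene-list association is the opposite: case-insensitive **exact token**
  equality, values split at `&`, `,` and `;`, because gene symbols must not
  cross-match (`BRCA1` vs `BRCA1P1`). A negative query keeps the working-set
  complement of the associated records; records with only missing symbols
  are not associated and are therefore kept.
* The `keep_missing` switch applies to records whose values for the queried
  field are all missing; toggling it partitions: result(true) is the
  disjoint union of result(false) and those records.
* Genotype classification is ploidy-independent and order-independent; a
  call containing any missing allele is MISSING and matches no class —
  there is no separate missingness quantifier.
* Symbolic and breakend alternates (`<DEL>`, `*`, `]17:198982]...`) are
  parsed and carried but classify as neither SNP, InDel nor MNP, so a
  variant-type filter never selects them.

Filters are applied sequentially; because each is a pure per-record
predicate, a chain's final set equals the intersection of the single-filter
answer sets and is invariant under reordering — both properties are tested
exhaustively over filter pairs, and every filter is checked against a naive
re-parse-and-scan oracle on seeded fixtures.

## History, deletion, export

Each applied filter appends a step (ordinal, type, parameter JSON, input
count, output count, UTC timestamp) whose output key set is persisted under
`workdir/steps/`. Recording enforces the telescoping invariant — a step's
input count must equal the previous step's output count — so engine/history
desynchronization fails loudly. Deleting step *k* truncates *k..n* rather
than splicing, because later outputs depend on earlier ones; the working set
reverts to step *k−1*. The plain-text report keeps the parameter JSON
verbatim in a tab-separated line, so a report is simultaneously
human-readable and mechanically replayable; replay reproduces every count.

TSV export writes the key columns (CHROM, POS, ID, REF, ALT) plus the
selected fields — the columns of the working table — one row per surviving
record in file order, multi-values joined by commas, missing rendered as
`nan`, embedded tabs/newlines replaced by spaces so the file stays
rectangular. The preview returns the top 100 rows by default.

## The simulator

`vcfsift.simulate` emulates the *structure* filtering has to cope with:
mixed SNP/InDel/MNP records (default mix 0.7/0.2/0.1), occasional
multi-allelic lines (rate 0.1) and duplicate positions (rate 0.02), missing
QUAL/INFO/genotype values (default rates 0.1–0.3; the oracle-battery
fixtures use 10% throughout), allele frequencies drawn log-uniformly over
10⁻⁴–1 so both rare and common variants occur, VEP-style CSQ strings with
1–4 transcript blocks and sporadically empty sub-fields, per-sample
ploidy of 1, 2 or 3, and phased separators on a fifth of heterozygous-style
calls. Every fixture ships a ground-truth sidecar (true kind per alternate
allele, true genotype class per sample, true annotation values) written at
construction time, so tests compare against what was built, not against the
code under test. Same seed, same bytes — gzip output uses a fixed mtime.

The trio preset plants exactly *k* rows with the de novo pattern (parents
`0/0`, child `0/1`) and redraws any other row that would match it by chance;
the tumour/normal preset does the analogue for hom-ref-in-normal. Recovery
is therefore exact by construction, which is the point: these tests verify
the filter logic, not a biological model. What the simulator does **not**
emulate: linkage, coalescent genealogies, realistic allele-frequency spectra,
strand or mapping artefacts, half-calls (`0/.` appears only via the missing
mechanism), or structural-variant alternates. Passing tests show the
filtering machinery is exact on structurally realistic input; they say
nothing about variant-calling quality upstream.

## Problem sizes and numerical choices

The test suite and the acceptance script run fixtures of 200–1000 variants
and 1–5 samples — large enough that every filter branch, arity and
missingness pattern occurs, small enough that the brute-force oracle can be
run on every one of them exhaustively. The battery covers 20 seeded
fixtures; chain semantics are checked on all 30 ordered filter pairs from a
6-spec pool; classification is checked against hand-enumerated truth tables
over all REF/ALT length combinations up to 3 and all 39 genotype index
vectors of ploidy ≤ 3 with indices ≤ 2.

Degenerate inputs: an empty VCF body yields an empty table, empty indexes
and empty filter results; an empty filter chain is the identity; a preview
of 0 rows is empty; `ALT=.` (monomorphic reference lines) parses to an
empty alternate list, whose `REF+ALT` cell is missing and which no
variant-type query selects. Malformed data lines (fewer than 8 columns,
non-integer POS) abort with an error naming the line number rather than
being skipped — silent skipping would make reported variant counts
untrustworthy, and the count chain is the backbone of the history report.

## Known limitations

BCF and tabix/remote access are out of scope, as is writing VCF output (the
export format is TSV). Compound-heterozygote detection, inheritance-model
solvers and allele-frequency computation from genotypes are deliberately
absent — this tool filters existing annotations, it does not create them.
The in-memory table loads the selected columns whole; for a whole-genome
VCF with many selected fields the workdir footprint scales with rows ×
fields, and field selection is the intended lever. Session state lives
entirely in the workdir; there is no cross-workdir session management.
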