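"""The five filters and the sequential chain, against hand-derived answers
on the five-record fixture plus property checks."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcfsift import (
    ConfigurationError,
    FieldOp,
    FieldPredicate,
    GeneListMode,
    GenotypeCall,
    GenotypeQuery,
    GtClass,
    Quantifier,
    StateError,
    VariantKind,
    WorkingSet,
    apply_chain,
    classify_genotype,
    classify_variant,
    filter_field,
    filter_gene_list,
    filter_genotype,
    filter_region,
    filter_variant_type,
)


def ranks(ws: WorkingSet) -> set[int]:
    return ws.ranks()


# --- classification --------------------------------------------------------

@pytest.mark.parametrize(
    "indices, expected",
    [
        ((0, 0), GtClass.HOM_REF),
        ((1, 1), GtClass.HOM_ALT),
        ((0, 1), GtClass.HET),
        ((1, 2), GtClass.HET),
        ((1,), GtClass.HOM_ALT),
        ((0,), GtClass.HOM_REF),
        ((0, 0, 1), GtClass.HET),
        ((2, 2, 2), GtClass.HOM_ALT),
        ((None, 1), GtClass.MISSING),
        ((None,), GtClass.MISSING),
    ],
)
def test_classify_genotype(indices, expected):
    call = GenotypeCall(indices, phased=False, raw="x")
    assert classify_genotype(call) is expected


def test_phasing_ignored_for_classification():
    a = GenotypeCall((0, 1), phased=True, raw="0|1")
    b = GenotypeCall((0, 1), phased=False, raw="0/1")
    assert classify_genotype(a) is classify_genotype(b) is GtClass.HET


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(0, 3), min_size=1, max_size=5), st.randoms(use_true_random=False))
def test_classification_invariant_under_allele_permutation(indices, rnd):
    base = classify_genotype(GenotypeCall(tuple(indices), False, "x"))
    shuffled = list(indices)
    rnd.shuffle(shuffled)
    assert classify_genotype(GenotypeCall(tuple(shuffled), False, "x")) is base


@pytest.mark.parametrize(
    "ref, alt, expected",
    [
        ("A", "G", VariantKind.SNP),
        ("AT", "GC", VariantKind.MNP),
        ("AT", "A", VariantKind.INDEL),
        ("A", "ATT", VariantKind.INDEL),
        ("A", "<DEL>", None),
        ("A", "*", None),
        ("G", "G]17:198982]", None),
    ],
)
def test_classify_variant(ref, alt, expected):
    assert classify_variant(ref, alt) is expected


# --- field filter ----------------------------------------------------------

def test_qual_greater_than_strict(hand_workspace, hand_ws):
    _, store = hand_workspace
    pred = FieldPredicate("QUAL", FieldOp.GREATER_THAN, 30, keep_missing=False)
    out = filter_field(hand_ws, pred, store)
    assert ranks(out) == {2, 4} and out.count == 2


def test_filter_equal_to_pass(hand_workspace, hand_ws):
    _, store = hand_workspace
    pred = FieldPredicate("FILTER", FieldOp.EQUAL_TO, "PASS")
    out = filter_field(hand_ws, pred, store)
    assert ranks(out) == {0, 2, 3}


def test_multi_keyword_consequence_query(hand_workspace, hand_ws):
    _, store = hand_workspace
    pred = FieldPredicate(
        "CSQ_Consequence", FieldOp.CONTAINS_KEYWORD,
        "missense,frameshift,stop_lost,stop_gained",
    )
    out = filter_field(hand_ws, pred, store)
    assert ranks(out) == {0, 1, 3}


def test_rare_or_absent_af_query(hand_workspace, hand_ws):
    """AF < 0.01 with keep_missing keeps rare AND database-absent variants."""
    _, store = hand_workspace
    strict = filter_field(
        hand_ws, FieldPredicate("AF", FieldOp.LESS_THAN, 0.01), store
    )
    assert ranks(strict) == {1}
    lenient = filter_field(
        hand_ws, FieldPredicate("AF", FieldOp.LESS_THAN, 0.01, keep_missing=True), store
    )
    assert ranks(lenient) == {1, 2, 4}


def test_numeric_equality_tolerates_formatting(hand_workspace, hand_ws):
    _, store = hand_workspace
    out = filter_field(
        hand_ws, FieldPredicate("QUAL", FieldOp.EQUAL_TO, "50.0"), store
    )
    assert ranks(out) == {2}


def test_inequality_requires_numeric_field(hand_workspace, hand_ws):
    _, store = hand_workspace
    with pytest.raises(ConfigurationError):
        filter_field(
            hand_ws, FieldPredicate("FILTER", FieldOp.GREATER_THAN, 1), store
        )


def test_unbuilt_index_is_state_error(hand_vcf, hand_ws, tmp_path):
    from conftest import build_workspace

    _, store = build_workspace(
        hand_vcf, tmp_path / "wd2", fields=["QUAL"], index_fields=[]
    )
    with pytest.raises(StateError):
        filter_field(hand_ws, FieldPredicate("QUAL", FieldOp.LESS_THAN, 5), store)


# --- genotype filter -------------------------------------------------------

def test_de_novo_trio_chain(hand_workspace, hand_ws):
    table, _ = hand_workspace
    parents = filter_genotype(
        hand_ws,
        GenotypeQuery(GtClass.HOM_REF, ("mother", "father"), Quantifier.ALL),
        table,
    )
    child = filter_genotype(
        parents, GenotypeQuery(GtClass.HET, ("child",), Quantifier.ALL), table
    )
    assert ranks(child) == {0}


def test_any_quantifier(hand_workspace, hand_ws):
    table, _ = hand_workspace
    out = filter_genotype(
        hand_ws,
        GenotypeQuery(GtClass.HET, ("mother", "father"), Quantifier.ANY),
        table,
    )
    # rank 3's mother is 1/2: two distinct non-reference alleles are HET
    assert ranks(out) == {1, 2, 3}


def test_missing_genotype_matches_no_class(hand_workspace, hand_ws):
    table, _ = hand_workspace
    # rank 2's mother is ./. — she matches neither HOM_REF nor anything else
    out = filter_genotype(
        hand_ws, GenotypeQuery(GtClass.HOM_REF, ("mother",), Quantifier.ALL), table
    )
    assert 2 not in ranks(out)
    assert ranks(out) == {0, 4}


def test_haploid_genotype_classified(hand_workspace, hand_ws):
    table, _ = hand_workspace
    # rank 3's child GT is "2" (haploid) -> HOM_ALT
    out = filter_genotype(
        hand_ws, GenotypeQuery(GtClass.HOM_ALT, ("child",), Quantifier.ALL), table
    )
    assert ranks(out) == {1, 3}


def test_unknown_sample_lists_valid_names(hand_workspace, hand_ws):
    table, _ = hand_workspace
    with pytest.raises(ConfigurationError, match="mother"):
        filter_genotype(
            hand_ws, GenotypeQuery(GtClass.HET, ("nobody",), Quantifier.ALL), table
        )


# --- region filter ---------------------------------------------------------

def test_region_closed_interval(hand_ws):
    out = filter_region(hand_ws, "1", 100, 200)
    assert ranks(out) == {0, 1, 2}  # both endpoints inclusive
    assert ranks(filter_region(hand_ws, "1", 101, 199)) == set()
    assert ranks(filter_region(hand_ws, "2", 100, 200)) == set()  # chrom literal


def test_region_start_after_end_rejected(hand_ws):
    with pytest.raises(ValueError):
        filter_region(hand_ws, "1", 200, 100)


# --- variant-type filter ---------------------------------------------------

def test_variant_type_any_match(hand_workspace, hand_ws):
    table, _ = hand_workspace
    assert ranks(filter_variant_type(hand_ws, VariantKind.SNP, table)) == {0, 3}
    assert ranks(filter_variant_type(hand_ws, VariantKind.INDEL, table)) == {1, 3}
    assert ranks(filter_variant_type(hand_ws, VariantKind.MNP, table)) == {2}


def test_symbolic_alt_matches_no_kind(hand_workspace, hand_ws):
    table, _ = hand_workspace
    for kind in VariantKind:
        assert 4 not in ranks(filter_variant_type(hand_ws, kind, table))


# --- gene-list filter ------------------------------------------------------

def test_gene_list_positive_negative_partition(hand_workspace, hand_ws):
    _, store = hand_workspace
    pos = filter_gene_list(
        hand_ws, ["BRCA2"], "CSQ_SYMBOL", GeneListMode.POSITIVE, store
    )
    neg = filter_gene_list(
        hand_ws, ["BRCA2"], "CSQ_SYMBOL", GeneListMode.NEGATIVE, store
    )
    assert ranks(pos) == {0, 1}
    assert ranks(neg) == {2, 3, 4}  # includes the CSQ-less record (missing)
    assert ranks(pos) | ranks(neg) == ranks(hand_ws)


def test_gene_match_case_insensitive_exact_token(hand_workspace, hand_ws):
    _, store = hand_workspace
    assert ranks(
        filter_gene_list(hand_ws, ["brca2"], "CSQ_SYMBOL", GeneListMode.POSITIVE, store)
    ) == {0, 1}
    # BRCA2 must not cross-match a BRCA1 query (exact token, not substring)
    assert ranks(
        filter_gene_list(hand_ws, ["BRCA1"], "CSQ_SYMBOL", GeneListMode.POSITIVE, store)
    ) == set()


# --- chain -----------------------------------------------------------------

CHAIN_SPECS = [
    {"type": "field", "field": "FILTER", "op": "equal_to", "value": "PASS"},
    {"type": "field", "field": "QUAL", "op": "greater_than", "value": 30},
]


def test_chain_counts_and_intersection(hand_workspace, hand_ws):
    table, store = hand_workspace
    out, history = apply_chain(hand_ws, CHAIN_SPECS, table, store)
    assert [(s.input_count, s.output_count) for s in history.steps] == [(5, 3), (3, 1)]
    assert ranks(out) == {2}
    # equals the intersection of the single-filter answers, in either order
    rev, _ = apply_chain(hand_ws, CHAIN_SPECS[::-1], table, store)
    assert ranks(rev) == ranks(out)


def test_empty_chain_is_identity(hand_workspace, hand_ws):
    table, store = hand_workspace
    out, history = apply_chain(hand_ws, [], table, store)
    assert out.keys == hand_ws.keys
    assert history.steps == []


def test_subset_invariant_along_chain(hand_workspace, hand_ws):
    table, store = hand_workspace
    specs = CHAIN_SPECS + [
        {"type": "variant_type", "kind": "SNP"},
        {"type": "region", "chrom": "1", "start": 1, "end": 10**9},
    ]
    ws = hand_ws
    for spec in specs:
        out, _ = apply_chain(ws, [spec], table, store)
        assert ranks(out) <= ranks(ws)
        ws = out


def test_keep_missing_partitions_working_set(hand_workspace, hand_ws):
    """result(keep_missing=True) is the disjoint union of
    result(keep_missing=False) and the all-missing keys."""
    _, store = hand_workspace
    for field, op, value in [("QUAL", FieldOp.GREATER_THAN, 30),
                             ("AF", FieldOp.LESS_THAN, 0.01),
                             ("CSQ_SYMBOL", FieldOp.CONTAINS_KEYWORD, "BRCA")]:
        without = filter_field(hand_ws, FieldPredicate(field, op, value), store)
        with_ = filter_field(
            hand_ws, FieldPredicate(field, op, value, keep_missing=True), store
        )
        missing = store.load(field).missing_ranks & ranks(hand_ws)
        assert ranks(with_) == ranks(without) | missing
        assert not (ranks(without) & missing)


def test_pairwise_order_invariance(hand_workspace, hand_ws):
    table, store = hand_workspace
    pool = CHAIN_SPECS + [
        {"type": "variant_type", "kind": "SNP"},
        {"type": "genotype", "gt_class": "HOM_REF", "samples": ["father"],
         "quantifier": "ALL"},
    ]
    for f1, f2 in itertools.permutations(pool, 2):
        a, _ = apply_chain(hand_ws, [f1, f2], table, store)
        b, _ = apply_chain(hand_ws, [f2, f1], table, store)
        assert ranks(a) == ranks(b)
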