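"""Filter history ledger, tail deletion, report round-trip and TSV export."""

import pytest

from vcfsift import (
    ConsistencyError,
    FilterHistory,
    FilterStep,
    FixtureSpec,
    WorkingSet,
    apply_chain,
    export_history,
    export_tsv,
    generate_vcf,
    preview,
)
from vcfsift.history_export import parse_history_report

from conftest import build_workspace

CHAIN = [
    {"type": "field", "field": "FILTER", "op": "equal_to", "value": "PASS"},
    {"type": "field", "field": "QUAL", "op": "greater_than", "value": 30},
    {"type": "variant_type", "kind": "SNP"},
]


def _step(ordinal, inp, out):
    return FilterStep(
        ordinal=ordinal, filter_type="field", parameters={"type": "field"},
        input_count=inp, output_count=out, timestamp="t",
        output_ranks=list(range(out)),
    )


def test_record_step_appends_and_persists(tmp_path):
    h = FilterHistory(base_count=10, workdir=tmp_path)
    h.record_step(_step(1, 10, 4))
    assert len(h.steps) == 1
    assert (tmp_path / h.steps[0].output_ref).is_file()
    reloaded = FilterHistory.load(tmp_path)
    assert reloaded.steps[0].output_count == 4
    assert reloaded.current_ranks() == list(range(4))


def test_record_step_rejects_count_mismatch():
    h = FilterHistory(base_count=10)
    with pytest.raises(ConsistencyError):
        h.record_step(_step(1, 9, 4))
    h.record_step(_step(1, 10, 4))
    with pytest.raises(ConsistencyError):
        h.record_step(_step(2, 10, 2))  # tail is 4, not 10
    with pytest.raises(ConsistencyError):
        h.record_step(_step(2, 4, 5))  # output above input


def test_three_step_chain_telescopes(hand_workspace, hand_ws):
    table, store = hand_workspace
    out, h = apply_chain(hand_ws, CHAIN, table, store)
    counts = [h.base_count] + [s.output_count for s in h.steps]
    assert counts == sorted(counts, reverse=True)
    for prev, step in zip(h.steps, h.steps[1:]):
        assert step.input_count == prev.output_count
    assert h.steps[-1].output_count == out.count


def test_delete_from_truncates_tail(tmp_path):
    h = FilterHistory(base_count=10, workdir=tmp_path)
    for i, (a, b) in enumerate([(10, 7), (7, 5), (5, 2)], start=1):
        h.record_step(_step(i, a, b))
    refs = [s.output_ref for s in h.steps]
    h.delete_from(2)
    assert [s.ordinal for s in h.steps] == [1]
    assert h.current_ranks() == list(range(7))
    assert (tmp_path / refs[0]).is_file()
    assert not (tmp_path / refs[1]).exists()
    assert not (tmp_path / refs[2]).exists()


def test_delete_first_step_reverts_to_base(tmp_path):
    h = FilterHistory(base_count=10, workdir=tmp_path)
    h.record_step(_step(1, 10, 3))
    h.delete_from(1)
    assert h.steps == []
    assert h.current_ranks() is None
    with pytest.raises(ValueError):
        h.delete_from(1)


def test_delete_then_reapply_reproduces_counts(hand_workspace, hand_ws):
    table, store = hand_workspace
    _, h1 = apply_chain(hand_ws, CHAIN, table, store)
    first = [s.output_count for s in h1.steps]
    h1.delete_from(2)
    ws = WorkingSet.from_table(table).restrict(set(h1.current_ranks()), "replay")
    _, h2 = apply_chain(ws, CHAIN[1:], table, store, history=h1)
    assert [s.output_count for s in h2.steps] == first


def test_history_report_round_trip(hand_workspace, hand_ws, tmp_path):
    table, store = hand_workspace
    out, h = apply_chain(hand_ws, CHAIN, table, store)
    h.source = table.source
    h.selected_fields = tuple(table.field_names)
    report = tmp_path / "history.txt"
    export_history(h, report)
    text = report.read_text()
    assert f"base variants: {h.base_count}" in text
    assert text.count("\n") >= len(CHAIN) + 4
    # the report reconstructs the exact step parameters...
    steps = parse_history_report(report)
    assert steps == CHAIN
    # ...and replaying them reproduces every count
    replay, h2 = apply_chain(hand_ws, steps, table, store)
    assert [s.output_count for s in h2.steps] == [s.output_count for s in h.steps]
    assert replay.keys == out.keys


def test_empty_history_report(tmp_path):
    h = FilterHistory(base_count=42, source="x.vcf")
    report = export_history(h, tmp_path / "r.txt")
    lines = report.read_text().splitlines()
    assert all(line.startswith("#") for line in lines)
    assert "base variants: 42" in lines[3]


def test_export_tsv_rectangular_and_count_conserving(hand_workspace, hand_ws, tmp_path):
    table, _ = hand_workspace
    out_path = export_tsv(hand_ws, table, tmp_path / "out.tsv")
    lines = out_path.read_text().splitlines()
    assert len(lines) == 1 + hand_ws.count
    widths = {len(line.split("\t")) for line in lines}
    assert widths == {5 + len(table.fields)}
    assert "nan" in lines[2].split("\t")  # missing QUAL of rank 1


def test_export_tsv_empty_working_set(hand_workspace, tmp_path):
    table, _ = hand_workspace
    empty = WorkingSet(())
    path = export_tsv(empty, table, tmp_path / "e.tsv")
    assert path.read_text().count("\n") == 1  # header only


def test_preview_defaults_to_top_100(tmp_path):
    spec = FixtureSpec(n_variants=250, seed=6)
    vcf, _ = generate_vcf(spec, tmp_path / "f.vcf")
    table, _ = build_workspace(vcf, tmp_path / "wd", fields=["QUAL"], index_fields=[])
    ws = WorkingSet.from_table(table)
    header, rows = preview(ws, table)
    assert len(rows) == 100
    assert rows[0][0] == table.rows[0].chrom
    assert len(preview(ws, table, n=5)[1]) == 5
    assert preview(ws, table, n=0)[1] == []


def test_preview_smaller_set_returned_whole(hand_workspace, hand_ws):
    table, _ = hand_workspace
    _, rows = preview(hand_ws, table, n=100)
    assert len(rows) == 5
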