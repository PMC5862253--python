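"""Filter history tracking and spreadsheet-compatible export.

Every applied filter is recorded as one ledger entry (type, parameters,
input count, output count, timestamp); the output key set of each step is
persisted to disk so any step — and everything after it, since each output
depends on its predecessor — can be deleted at any time, reverting the
working set.  The history is stored as machine-replayable JSON beside the
workdir manifest and rendered as a plain-text report for record-keeping;
the current variants export as a tab-separated file any spreadsheet opens.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path

from .errors import ConsistencyError
from .preprocess import PreprocessedTable
from .filter_engine import WorkingSet

HISTORY_NAME = "history.json"
STEPS_DIR = "steps"


def utc_now_iso() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class FilterStep:
    """One applied filter: its serialized specification plus the count it
    received and the count it produced."""

    ordinal: int
    filter_type: str
    parameters: dict
    input_count: int
    output_count: int
    timestamp: str
    output_ref: str | None = None
    output_ranks: list[int] | None = dc_field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "ordinal": self.ordinal,
            "filter_type": self.filter_type,
            "parameters": self.parameters,
            "input_count": self.input_count,
            "output_count": self.output_count,
            "timestamp": self.timestamp,
            "output_ref": self.output_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterStep":
        return cls(**d)


class FilterHistory:
    """Ordered ledger of applied filters with telescoping counts.

    With a ``workdir`` the history and each step's output key set persist to
    disk; without one it is an in-memory ledger (used by one-shot chains).
    """

    def __init__(
        self,
        base_count: int,
        workdir: str | Path | None = None,
        source: str = "",
        selected_fields: tuple[str, ...] = (),
    ):
        self.base_count = base_count
        self.workdir = Path(workdir) if workdir is not None else None
        self.source = source
        self.selected_fields = tuple(selected_fields)
        self.steps: list[FilterStep] = []
        self._ranks: dict[int, list[int]] = {}  # ordinal -> output ranks

    # -- recording ---------------------------------------------------------

    def tail_count(self) -> int:
        return self.steps[-1].output_count if self.steps else self.base_count

    def record_step(self, step: FilterStep) -> "FilterHistory":
        if step.input_count != self.tail_count():
            raise ConsistencyError(
                f"step input count {step.input_count} does not match the current "
                f"working-set count {self.tail_count()}"
            )
        if step.output_count > step.input_count:
            raise ConsistencyError(
                f"step output count {step.output_count} exceeds its input "
                f"count {step.input_count}"
            )
        step.ordinal = len(self.steps) + 1
        self.steps.append(step)
        if step.output_ranks is not None:
            self._ranks[step.ordinal] = list(step.output_ranks)
        if self.workdir is not None:
            self._persist_step(step)
            self.save()
        return self

    def _persist_step(self, step: FilterStep) -> None:
        assert self.workdir is not None
        steps_dir = self.workdir / STEPS_DIR
        steps_dir.mkdir(parents=True, exist_ok=True)
        ref = f"{STEPS_DIR}/step_{step.ordinal:04d}.json"
        with open(self.workdir / ref, "w", encoding="utf-8") as fh:
            json.dump({"ordinal": step.ordinal, "ranks": step.output_ranks}, fh)
        step.output_ref = ref

    # -- deletion ----------------------------------------------------------

    def delete_from(self, ordinal: int) -> "FilterHistory":
        """Delete step ``ordinal`` and every later step (their outputs depend
        on it); the working set reverts to the preceding step's output."""
        if not 1 <= ordinal <= len(self.steps):
            raise ValueError(
                f"ordinal {ordinal} out of range 1..{len(self.steps)}"
            )
        for step in self.steps[ordinal - 1 :]:
            self._ranks.pop(step.ordinal, None)
            if self.workdir is not None and step.output_ref:
                (self.workdir / step.output_ref).unlink(missing_ok=True)
        self.steps = self.steps[: ordinal - 1]
        if self.workdir is not None:
            self.save()
        return self

    # -- current working set -----------------------------------------------

    def current_ranks(self) -> list[int] | None:
        """Output ranks of the last step, or None when no filter is applied."""
        if not self.steps:
            return None
        ordinal = self.steps[-1].ordinal
        if ordinal in self._ranks:
            return self._ranks[ordinal]
        if self.workdir is not None and self.steps[-1].output_ref:
            with open(self.workdir / self.steps[-1].output_ref, encoding="utf-8") as fh:
                ranks = json.load(fh)["ranks"]
            self._ranks[ordinal] = ranks
            return ranks
        raise ConsistencyError(f"output of step {ordinal} was not persisted")

    def current_working_set(self, table: PreprocessedTable) -> WorkingSet:
        ranks = self.current_ranks()
        base = WorkingSet.from_table(table)
        if ranks is None:
            return base
        return base.restrict(set(ranks), origin=f"after step {self.steps[-1].ordinal}")

    # -- persistence ---------------------------------------------------------

    def save(self) -> None:
        assert self.workdir is not None
        payload = {
            "base_count": self.base_count,
            "source": self.source,
            "selected_fields": list(self.selected_fields),
            "steps": [s.to_dict() for s in self.steps],
        }
        tmp = self.workdir / (HISTORY_NAME + ".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        shutil.move(tmp, self.workdir / HISTORY_NAME)

    @classmethod
    def load(cls, workdir: str | Path) -> "FilterHistory":
        workdir = Path(workdir)
        path = workdir / HISTORY_NAME
        if not path.is_file():
            return cls(base_count=0, workdir=workdir)
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        hist = cls(
            base_count=payload["base_count"],
            workdir=workdir,
            source=payload.get("source", ""),
            selected_fields=tuple(payload.get("selected_fields", ())),
        )
        hist.steps = [FilterStep.from_dict(d) for d in payload["steps"]]
        return hist


def record_step(history: FilterHistory, step: FilterStep) -> FilterHistory:
    return history.record_step(step)


def delete_from(history: FilterHistory, ordinal: int) -> FilterHistory:
    return history.delete_from(ordinal)


def export_history(history: FilterHistory, path: str | Path) -> Path:
    """Write the query history as a human-readable plain-text report.

    Step lines are tab-separated (ordinal, type, parameter JSON, input count,
    output count, timestamp) so the report is both readable and mechanically
    re-parseable for replay.
    """
    path = Path(path)
    lines = [
        "# vcfsift filter history",
        f"# source: {history.source or '(unknown)'}",
        f"# selected fields: {', '.join(history.selected_fields) or '(none)'}",
        f"# base variants: {history.base_count}",
        "# ordinal\ttype\tparameters\tinput\toutput\ttimestamp",
    ]
    for s in history.steps:
        params = json.dumps(s.parameters, sort_keys=True)
        lines.append(
            f"{s.ordinal}\t{s.filter_type}\t{params}\t{s.input_count}\t"
            f"{s.output_count}\t{s.timestamp}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def parse_history_report(path: str | Path) -> list[dict]:
    """Reconstruct the step specifications from an exported report."""
    steps = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        _, _, params, _, _, _ = line.split("\t")
        steps.append(json.loads(params))
    return steps


def _sanitize(value: str) -> str:
    return value.replace("\t", " ").replace("\n", " ").replace("\r", " ")


def _export_columns(table: PreprocessedTable) -> list[str]:
    return ["CHROM", "POS", "ID", "REF", "ALT"] + [
        f.name for f in table.fields
    ]


def _export_row(table: PreprocessedTable, rank: int) -> list[str]:
    row = table.row(rank)
    cells = [
        row.chrom,
        str(row.pos),
        row.id,
        row.ref,
        ",".join(row.alts) if row.alts else ".",
    ]
    for f in table.fields:
        cells.append(_sanitize(",".join(row.cells[f.name])))
    return cells


def export_tsv(ws: WorkingSet, table: PreprocessedTable, path: str | Path) -> Path:
    """Tab-separated export of the current variants (header + one row per
    surviving key, in file order); missing values render as "nan"."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_export_columns(table)) + "\n")
        for key in ws.keys:
            fh.write("\t".join(_export_row(table, key.rank)) + "\n")
    return path


def preview(
    ws: WorkingSet, table: PreprocessedTable, n: int = 100
) -> tuple[list[str], list[list[str]]]:
    """First ``min(n, count)`` rows in file order (header, rows)."""
    if n < 0:
        raise ValueError("preview size must be >= 0")
    header = _export_columns(table)
    rows = [_export_row(table, key.rank) for key in ws.keys[:n]]
    return header, rows
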