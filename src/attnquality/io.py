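"""Data model and tabular I/O for selective-attention (NTT-style) response sequences.

A participant sits a fixed-duration cancellation test split into two tasks
and produces an ordered stream of decisions.  Each decision carries a symbol
(``Y``/``N``/``I`` for yes / no / ignore), a correctness flag and a reaction
time in milliseconds.  The interchange format is a flat CSV with one row per
decision event and the canonical columns::

    participant_id,task_index,event_index,decision,correct,reaction_time_ms

XLSX files with the same columns are accepted read-only (to ingest deposited
spreadsheets); the package always writes CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DECISION_SYMBOLS = ("Y", "N", "I")

#: canonical column order of the interchange CSV
COLUMNS = (
    "participant_id",
    "task_index",
    "event_index",
    "decision",
    "correct",
    "reaction_time_ms",
)

#: number-of-decisions range the test protocol is designed for
NOD_RANGE = (200, 800)


class FormatError(ValueError):
    """A structural problem with an input file (missing column, bad token)."""


@dataclass(frozen=True)
class ResponseEvent:
    """One decision: symbol, correctness and reaction time (ms)."""

    decision: str
    correct: bool
    reaction_time_ms: float

    def __post_init__(self) -> None:
        if self.decision not in DECISION_SYMBOLS:
            raise FormatError(
                f"decision symbol must be one of {DECISION_SYMBOLS}, got {self.decision!r}"
            )
        if not self.reaction_time_ms > 0:
            raise FormatError(
                f"reaction time must be positive, got {self.reaction_time_ms!r}"
            )


@dataclass
class ResponseSequence:
    """One participant's ordered decisions, grouped by task.

    ``tasks`` preserves collection order both across tasks and within each
    task.  The total event count is the participant's number of decisions
    (NoD); a warning is issued when it falls outside the protocol range
    [200, 800], since the test is specified to yield counts in that range.
    """

    participant_id: str
    tasks: list[list[ResponseEvent]]

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError(f"participant {self.participant_id!r} has no tasks")
        if not (NOD_RANGE[0] <= self.nod <= NOD_RANGE[1]):
            warnings.warn(
                f"participant {self.participant_id!r}: NoD={self.nod} outside "
                f"the protocol range {NOD_RANGE}",
                stacklevel=2,
            )

    @property
    def events(self) -> list[ResponseEvent]:
        """All events across tasks, in collection order."""
        return [e for task in self.tasks for e in task]

    @property
    def nod(self) -> int:
        """Number of decisions across all tasks."""
        return sum(len(t) for t in self.tasks)

    @property
    def reaction_times(self) -> list[float]:
        return [e.reaction_time_ms for e in self.events]


@dataclass
class Cohort:
    """A list of response sequences with provenance metadata.

    ``provenance`` records the source path and the cleaning log (one line per
    dropped row or removed participant) so a processed cohort is auditable.
    """

    sequences: list[ResponseSequence]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.sequences]

    @property
    def cleaning_log(self) -> list[str]:
        return self.provenance.setdefault("cleaning_log", [])

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical one-row-per-event table."""
        rows = []
        for seq in self.sequences:
            for t, task in enumerate(seq.tasks):
                for i, ev in enumerate(task):
                    rows.append(
                        (seq.participant_id, t, i, ev.decision, ev.correct,
                         ev.reaction_time_ms)
                    )
        return pd.DataFrame(rows, columns=list(COLUMNS))


@dataclass(frozen=True)
class CleaningRules:
    """Participant-level exclusion rules.

    The deposited study data does not state the rule that removed its
    excluded records, so these defaults are a documented stand-in: keep
    participants with at least ``min_tasks`` tasks, a total NoD of at least
    ``min_nod`` and at most ``max_missing_fraction`` of their rows dropped
    during reading.
    """

    min_nod: int = 100
    min_tasks: int = 2
    max_missing_fraction: float = 1.0


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    token = str(value).strip().lower()
    if token in ("true", "t", "1", "yes"):
        return True
    if token in ("false", "f", "0", "no"):
        return False
    raise FormatError(f"cannot interpret correctness flag {value!r}")


def read_cohort(path: str | Path, format: str | None = None, *,
                strict: bool = False) -> Cohort:
    """Read a cohort from a CSV or XLSX event table.

    Rows whose decision symbol is outside ``{Y, N, I}`` or whose reaction
    time is not positive are rejected and logged; with ``strict=True`` the
    first such row aborts the read with its row number.  Events are ordered
    by ``(task_index, event_index)`` within each participant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    log: list[str] = []
    dropped_per_participant: dict[str, int] = {}
    keep = []
    for pos, row in enumerate(df.itertuples(index=False)):
        # header is line 1, so data row `pos` is file line pos + 2
        line = pos + 2
        pid = str(row.participant_id)
        problem = None
        decision = str(row.decision).strip()
        if decision not in DECISION_SYMBOLS:
            problem = f"decision token {row.decision!r}"
        else:
            try:
                rt = float(row.reaction_time_ms)
            except (TypeError, ValueError):
                rt = float("nan")
            if not rt > 0:
                problem = f"non-positive reaction time {row.reaction_time_ms!r}"
        if problem is not None:
            if strict:
                raise FormatError(f"row {line}: {problem}")
            log.append(f"dropped row {line} (participant {pid}): {problem}")
            dropped_per_participant[pid] = dropped_per_participant.get(pid, 0) + 1
            continue
        keep.append(pos)

    df = df.iloc[keep]
    sequences = []
    for pid, group in df.groupby("participant_id", sort=False):
        group = group.sort_values(["task_index", "event_index"], kind="stable")
        tasks = []
        for _, task_rows in group.groupby("task_index", sort=True):
            tasks.append(
                [ResponseEvent(str(r.decision).strip(), _parse_bool(r.correct),
                               float(r.reaction_time_ms))
                 for r in task_rows.itertuples(index=False)]
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # NoD range warning handled downstream
            sequences.append(ResponseSequence(str(pid), tasks))

    return Cohort(
        sequences,
        provenance={
            "source": str(path),
            "cleaning_log": log,
            "dropped_rows": dropped_per_participant,
        },
    )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as a canonical CSV (header always present)."""
    cohort.to_frame().to_csv(path, index=False)


def clean_cohort(cohort: Cohort, rules: CleaningRules | None = None) -> Cohort:
    """Remove participants that violate the cleaning rules.

    Idempotent; the returned cohort's log contains one line per removal with
    the rule that triggered it.  An empty result is allowed (with a warning).
    """
    rules = rules or CleaningRules()
    dropped_rows = cohort.provenance.get("dropped_rows", {})
    log = list(cohort.provenance.get("cleaning_log", []))
    kept = []
    for seq in cohort.sequences:
        reason = None
        if len(seq.tasks) < rules.min_tasks:
            reason = f"tasks={len(seq.tasks)} < min_tasks={rules.min_tasks}"
        elif seq.nod < rules.min_nod:
            reason = f"NoD={seq.nod} < min_nod={rules.min_nod}"
        else:
            n_drop = dropped_rows.get(seq.participant_id, 0)
            frac = n_drop / (n_drop + seq.nod) if (n_drop + seq.nod) else 0.0
            if frac > rules.max_missing_fraction:
                reason = (f"missing fraction {frac:.3f} > "
                          f"max {rules.max_missing_fraction}")
        if reason is None:
            kept.append(seq)
        else:
            log.append(f"removed participant {seq.participant_id}: {reason}")
    if not kept:
        warnings.warn("cleaning removed every participant", stacklevel=2)
    provenance = dict(cohort.provenance)
    provenance["cleaning_log"] = log
    provenance["rules"] = rules
    return Cohort(kept, provenance=provenance)


def cohorts_equal(a: Cohort, b: Cohort, *, rtol: float = 1e-9) -> bool:
    """Structural equality of two cohorts (ids, order, symbols, times)."""
    if a.participant_ids() != b.participant_ids():
        return False
    for sa, sb in zip(a.sequences, b.sequences):
        if len(sa.tasks) != len(sb.tasks):
            return False
        for ta, tb in zip(sa.tasks, sb.tasks):
            if len(ta) != len(tb):
                return False
            for ea, eb in zip(ta, tb):
                if ea.decision != eb.decision or ea.correct != eb.correct:
                    return False
                denom = max(abs(ea.reaction_time_ms), abs(eb.reaction_time_ms), 1.0)
                if abs(ea.reaction_time_ms - eb.reaction_time_ms) > rtol * denom:
                    return False
    return True
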