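"""Canonical data model for two-alternative forced-choice (2AFC) choice-learning
experiments.

A trial is a single self-paced episode: the rat initiates at a center port, one
(single-offer) or both (dual-offer) lateral luminance cues light up, and the rat
pokes a side port.  The table schema is deliberately flat — one row per trial —
so that cohorts of many rats and sessions live in a single CSV file.

The canonical CSV dialect is UTF-8, comma-separated, with a header row and
seconds stored as decimal floats.  Session and trial indices are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "TrialRecord",
    "TrialDataset",
    "ValidationIssue",
    "ValidationReport",
    "SchemaError",
    "TrialParseError",
    "read_trial_table",
    "write_trial_table",
    "validate_dataset",
    "CANONICAL_COLUMNS",
]

PHASES = ("value_learning", "choice_learning")
TRIAL_TYPES = ("single", "dual")
SIDES = ("left", "right")
CHOICES = ("high", "low", "none")

CANONICAL_COLUMNS = (
    "rat_id",
    "phase",
    "session_index",
    "trial_index",
    "trial_type",
    "offered_high",
    "offered_low",
    "high_side",
    "chosen",
    "is_error",
    "latency_s",
    "trial_start_s",
)


class SchemaError(ValueError):
    """The file's header does not match the canonical column set."""


class TrialParseError(ValueError):
    """A row holds a value that cannot be interpreted; carries the row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    ``latency_s`` is the time from trial initiation (center poke) to the lateral
    nosepoke; ``trial_start_s`` is the trial's onset measured from session start.
    Error trials (a poke at the non-illuminated port on a single-offer trial)
    carry ``chosen="none"`` and ``is_error=True``.
    """

    rat_id: str
    phase: str
    session_index: int
    trial_index: int
    trial_type: str
    offered_high: bool
    offered_low: bool
    high_side: str
    chosen: str
    is_error: bool
    latency_s: float
    trial_start_s: float

    def violations(self) -> list[str]:
        v: list[str] = []
        if self.phase not in PHASES:
            v.append(f"phase {self.phase!r} not in {PHASES}")
        if self.trial_type not in TRIAL_TYPES:
            v.append(f"trial_type {self.trial_type!r} not in {TRIAL_TYPES}")
        if self.high_side not in SIDES:
            v.append(f"high_side {self.high_side!r} not in {SIDES}")
        if self.chosen not in CHOICES:
            v.append(f"chosen {self.chosen!r} not in {CHOICES}")
        if self.session_index < 1:
            v.append("session_index must be >= 1")
        if self.trial_index < 1:
            v.append("trial_index must be >= 1")
        if self.trial_type == "single" and not (self.offered_high ^ self.offered_low):
            v.append("single-offer trial must offer exactly one stimulus")
        if self.trial_type == "dual" and not (self.offered_high and self.offered_low):
            v.append("dual-offer trial must offer both stimuli")
        if self.trial_type == "dual":
            if self.is_error:
                v.append("dual-offer trials cannot be error trials")
            if self.chosen not in ("high", "low"):
                v.append("dual-offer trial must have chosen in {'high','low'}")
        if self.trial_type == "single" and not self.is_error:
            offered = "high" if self.offered_high else "low"
            if self.chosen != offered:
                v.append(
                    f"correct single-offer trial must have chosen={offered!r}, "
                    f"got {self.chosen!r}"
                )
        if self.is_error and self.chosen != "none":
            v.append("error trial must have chosen='none'")
        if not self.latency_s >= 0:
            v.append(f"latency_s must be >= 0, got {self.latency_s}")
        if not self.trial_start_s >= 0:
            v.append(f"trial_start_s must be >= 0, got {self.trial_start_s}")
        return v

    @property
    def value(self) -> str | None:
        """Reward value addressed by the trial's response, or offered stimulus
        on single-offer trials; ``None`` for error trials."""
        if self.trial_type == "single":
            return "high" if self.offered_high else "low"
        return self.chosen if self.chosen in ("high", "low") else None


@dataclass
class TrialDataset:
    """Ordered collection of trials plus provenance metadata."""

    trials: list[TrialRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        if not self.trials:
            return pd.DataFrame(columns=list(CANONICAL_COLUMNS))
        df = pd.DataFrame([t.__dict__ for t in self.trials])
        return df[list(CANONICAL_COLUMNS)]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "TrialDataset":
        trials = [
            TrialRecord(
                rat_id=str(r.rat_id),
                phase=str(r.phase),
                session_index=int(r.session_index),
                trial_index=int(r.trial_index),
                trial_type=str(r.trial_type),
                offered_high=bool(r.offered_high),
                offered_low=bool(r.offered_low),
                high_side=str(r.high_side),
                chosen=str(r.chosen),
                is_error=bool(r.is_error),
                latency_s=float(r.latency_s),
                trial_start_s=float(r.trial_start_s),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(trials=trials, meta=dict(meta or {}))

    def filtered(self, predicate) -> "TrialDataset":
        return TrialDataset(
            trials=[t for t in self.trials if predicate(t)], meta=dict(self.meta)
        )


@dataclass(frozen=True)
class ValidationIssue:
    """A single invariant violation, addressed to the trial that carries it."""

    rat_id: str | None
    session_index: int | None
    trial_index: int | None
    message: str

    def to_dict(self) -> dict:
        return {
            "rat_id": self.rat_id,
            "session_index": self.session_index,
            "trial_index": self.trial_index,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def to_json(self) -> str:
        return json.dumps([i.to_dict() for i in self.issues], indent=2)


_BOOL_STRINGS = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(raw: str, row: int, column: str) -> bool:
    try:
        return _BOOL_STRINGS[raw.strip().lower()]
    except KeyError:
        raise TrialParseError(row, f"column {column!r}: {raw!r} is not a boolean")


def _parse_float(raw: str, row: int, column: str, nonneg: bool = False) -> float:
    try:
        val = float(raw)
    except ValueError:
        raise TrialParseError(row, f"column {column!r}: {raw!r} is not a number")
    if nonneg and not val >= 0:
        raise TrialParseError(row, f"column {column!r}: {val} must be >= 0")
    return val


def _parse_int(raw: str, row: int, column: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise TrialParseError(row, f"column {column!r}: {raw!r} is not an integer")


def read_trial_table(path: str | Path, dialect: str = "canonical_csv") -> TrialDataset:
    """Read a canonical trial CSV into a :class:`TrialDataset`.

    Every row becomes a :class:`TrialRecord`; nothing is silently dropped.
    Raises :class:`SchemaError` for header mismatches and
    :class:`TrialParseError` (with the 1-based data row number) for bad values.
    """
    if dialect != "canonical_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    unknown = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")

    trials: list[TrialRecord] = []
    for i, r in enumerate(df.itertuples(index=False), start=1):
        rec = TrialRecord(
            rat_id=r.rat_id,
            phase=r.phase,
            session_index=_parse_int(r.session_index, i, "session_index"),
            trial_index=_parse_int(r.trial_index, i, "trial_index"),
            trial_type=r.trial_type,
            offered_high=_parse_bool(r.offered_high, i, "offered_high"),
            offered_low=_parse_bool(r.offered_low, i, "offered_low"),
            high_side=r.high_side,
            chosen=r.chosen,
            is_error=_parse_bool(r.is_error, i, "is_error"),
            latency_s=_parse_float(r.latency_s, i, "latency_s", nonneg=True),
            trial_start_s=_parse_float(r.trial_start_s, i, "trial_start_s", nonneg=True),
        )
        bad = rec.violations()
        if bad:
            raise TrialParseError(i, "; ".join(bad))
        trials.append(rec)
    return TrialDataset(trials=trials, meta={"source": str(path), "dialect": dialect})


def write_trial_table(dataset: TrialDataset, path: str | Path) -> None:
    """Write a dataset as canonical CSV; ``read_trial_table`` inverts it.

    Refuses to write datasets that violate the trial or dataset invariants.
    """
    report = validate_dataset(dataset)
    if not report.ok:
        raise ValueError(
            f"dataset has {len(report)} invariant violation(s); first: "
            f"{report.issues[0].message}"
        )
    df = dataset.to_frame()
    # repr round-trips floats exactly; booleans lower-cased for stability
    out = df.copy()
    for col in ("offered_high", "offered_low", "is_error"):
        out[col] = out[col].map(lambda b: "true" if b else "false")
    for col in ("latency_s", "trial_start_s"):
        out[col] = out[col].map(repr)
    out.to_csv(path, index=False)


def validate_dataset(dataset: TrialDataset) -> ValidationReport:
    """Check every trial- and dataset-level invariant; violations are data."""
    issues: list[ValidationIssue] = []
    for t in dataset.trials:
        for msg in t.violations():
            issues.append(ValidationIssue(t.rat_id, t.session_index, t.trial_index, msg))

    seen: dict[tuple, TrialRecord] = {}
    for t in dataset.trials:
        key = (t.rat_id, t.phase, t.session_index, t.trial_index)
        if key in seen:
            issues.append(
                ValidationIssue(
                    t.rat_id, t.session_index, t.trial_index,
                    f"duplicate trial key {key}",
                )
            )
        seen[key] = t

    # trial_start_s strictly increasing with trial_index within a session
    by_session: dict[tuple, list[TrialRecord]] = {}
    for t in dataset.trials:
        by_session.setdefault((t.rat_id, t.phase, t.session_index), []).append(t)
    for (rat, phase, sess), ts in by_session.items():
        ts_sorted = sorted(ts, key=lambda t: t.trial_index)
        for a, b in zip(ts_sorted, ts_sorted[1:]):
            if not b.trial_start_s > a.trial_start_s:
                issues.append(
                    ValidationIssue(
                        rat, sess, b.trial_index,
                        "trial_start_s not strictly increasing with trial_index",
                    )
                )
    return ValidationReport(issues=issues)
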