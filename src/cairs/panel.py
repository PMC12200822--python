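"""Panel I/O: reading, validating and deriving two-time-point ordinal panels.

A panel holds one row per individual with a complete profile at baseline and
one follow-up visit.  The CSV dialect is flat and diff-able: columns
``<domain>_t0`` and ``<domain>_t1`` for every registered domain, plus
optional ``id`` and ``days_between`` columns.  Level labels are read
case-insensitively and written lower-case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .domains import (
    LEVELS,
    DomainRegistry,
    ProfileState,
    normalize_level,
)

__all__ = [
    "PanelRecord",
    "PanelDataset",
    "Visit",
    "PanelSchemaError",
    "PanelParseError",
    "PanelValidationError",
    "read_panel_csv",
    "write_panel_csv",
    "select_followup",
    "category_table",
]


class PanelSchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class PanelParseError(ValueError):
    """A cell value could not be interpreted as a level label."""


class PanelValidationError(ValueError):
    """Structurally valid input violating a dataset invariant."""


@dataclass(frozen=True)
class PanelRecord:
    """One individual: baseline and follow-up profile plus the gap in days."""

    individual_id: str
    baseline: ProfileState
    followup: ProfileState
    days_between: int = 0

    def __post_init__(self) -> None:
        if self.days_between < 0:
            raise PanelValidationError(
                f"days_between must be nonnegative, got {self.days_between}"
            )
        if self.baseline.registry != self.followup.registry:
            raise PanelValidationError("baseline/followup registries differ")


@dataclass(frozen=True)
class PanelDataset:
    """Ordered collection of panel records over a shared domain registry."""

    registry: DomainRegistry
    records: tuple[PanelRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise PanelValidationError("panel must contain at least one record")
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate individual_id values: {dup}")
        for r in self.records:
            if r.baseline.registry != self.registry:
                raise PanelValidationError("record registry differs from panel registry")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame in the documented CSV dialect (lower-case labels)."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {"id": r.individual_id}
            for d in self.registry:
                row[f"{d}_t0"] = LEVELS[r.baseline.level(d)]
                row[f"{d}_t1"] = LEVELS[r.followup.level(d)]
            row["days_between"] = r.days_between
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, registry: DomainRegistry
    ) -> "PanelDataset":
        return _parse_frame(frame, registry)

    def codes(self) -> np.ndarray:
        """(n, 2k) integer matrix: baseline codes then follow-up codes."""
        k = len(self.registry)
        out = np.empty((len(self.records), 2 * k), dtype=np.int64)
        for i, r in enumerate(self.records):
            out[i, :k] = r.baseline.levels
            out[i, k:] = r.followup.levels
        return out

    def baseline_states(self) -> list[ProfileState]:
        return [r.baseline for r in self.records]


def _parse_frame(frame: pd.DataFrame, registry: DomainRegistry) -> PanelDataset:
    missing = [
        col
        for d in registry
        for col in (f"{d}_t0", f"{d}_t1")
        if col not in frame.columns
    ]
    if missing:
        raise PanelSchemaError(f"panel is missing required columns: {missing}")

    has_id = "id" in frame.columns
    has_days = "days_between" in frame.columns
    records = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        levels = {}
        for d in registry:
            for suffix in ("t0", "t1"):
                col = f"{d}_{suffix}"
                try:
                    levels[col] = normalize_level(row[col])
                except ValueError as exc:
                    raise PanelParseError(
                        f"row {pos}, column {col!r}: {exc}"
                    ) from None
        baseline = ProfileState(registry, tuple(levels[f"{d}_t0"] for d in registry))
        followup = ProfileState(registry, tuple(levels[f"{d}_t1"] for d in registry))
        ind = str(row["id"]) if has_id else str(pos)
        days = int(row["days_between"]) if has_days else 0
        records.append(PanelRecord(ind, baseline, followup, days))
    return PanelDataset(registry, tuple(records))


def read_panel_csv(
    path: str | Path, registry: DomainRegistry | None = None
) -> PanelDataset:
    """Read a panel CSV into a validated :class:`PanelDataset`.

    Row order is preserved.  Raises :class:`PanelSchemaError` for missing
    columns, :class:`PanelParseError` for unknown level labels (with row
    number), :class:`PanelValidationError` for duplicate ids.
    """
    registry = registry or DomainRegistry()
    frame = pd.read_csv(path, dtype=str)
    if "days_between" in frame.columns:
        frame["days_between"] = frame["days_between"].astype(int)
    return _parse_frame(frame, registry)


def write_panel_csv(panel: PanelDataset, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class Visit:
    """A dated questionnaire completion for one individual."""

    individual_id: str
    day: int
    state: ProfileState


def select_followup(
    visits: Sequence[Visit],
    min_days: int = 7,
    max_days: int = 183,
) -> tuple[PanelDataset, int]:
    """Apply the baseline/follow-up selection rule to dated visit sequences.

    Baseline is each individual's first visit; follow-up is the earliest
    later visit with ``min_days <= gap <= max_days`` (defaults one week to
    six months).  Individuals without such a visit are dropped.

    Returns the resulting panel and the number of dropped individuals.
    Raises :class:`PanelValidationError` if any individual's visits are not
    sorted by day, or if ``min_days >= max_days``.
    """
    if min_days >= max_days:
        raise PanelValidationError(
            f"min_days ({min_days}) must be < max_days ({max_days})"
        )
    by_individual: dict[str, list[Visit]] = {}
    for v in visits:
        by_individual.setdefault(v.individual_id, []).append(v)

    records = []
    dropped = 0
    for ind, seq in by_individual.items():
        days = [v.day for v in seq]
        if days != sorted(days):
            raise PanelValidationError(f"visits for individual {ind!r} are unsorted")
        base = seq[0]
        chosen = None
        for v in seq[1:]:
            gap = v.day - base.day
            if min_days <= gap <= max_days:
                chosen = v
                break
        if chosen is None:
            dropped += 1
            continue
        records.append(
            PanelRecord(ind, base.state, chosen.state, chosen.day - base.day)
        )
    if not records:
        raise PanelValidationError("no individual has a follow-up inside the window")
    registry = records[0].baseline.registry
    return PanelDataset(registry, tuple(records)), dropped


def category_table(panel: PanelDataset) -> pd.DataFrame:
    """Per-domain, per-slice counts of each level.

    Returns a DataFrame indexed by (domain, slice) with columns
    ``poor``/``fair``/``healthy``; each row sums to ``panel.n``.
    """
    codes = panel.codes()
    k = len(panel.registry)
    rows = []
    index = []
    for j, d in enumerate(panel.registry):
        for s, name in ((0, "baseline"), (1, "followup")):
            col = codes[:, j + s * k]
            counts = np.bincount(col, minlength=3)
            rows.append(counts)
            index.append((d, name))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["domain", "slice"]),
        columns=list(LEVELS),
    )
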