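"""Data model, validation and delimited-text I/O for longitudinal panels.

A panel is stored in long format: one row per person x timepoint, one column
per declared measure column, plus an optional per-person ordinal outcome.
Missing cells are kept as NaN in the values frame; the boolean mask is derived
on demand and round-trips through CSV (empty field or ``NA`` on read, empty
field on write).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FACTOR_NAMES",
    "PanelSchema",
    "PanelValidationError",
    "RawPanel",
    "FactorPanel",
    "read_panel",
    "write_panel",
    "read_factor_panel",
    "write_factor_panel",
]

#: Fixed order of the four operating factors used everywhere downstream.
FACTOR_NAMES = (
    "net_hope",
    "technical_skills",
    "physical_fitness",
    "biological_maturity",
)

PERSON_COL = "person_id"
TIME_COL = "timepoint"
OUTCOME_COL = "outcome"

#: Tokens accepted as missing on read; the empty field is written.
MISSING_TOKENS = ("", "NA")


class PanelValidationError(ValueError):
    """Raised when a panel file or in-memory panel violates the data contract."""


@dataclass(frozen=True)
class VariableDecl:
    """Declaration of one measured test.

    orientation
        ``"higher"`` if larger raw values mean better performance (jump
        height, endurance distance, juggling points, percent adult height),
        ``"lower"`` if smaller values do (sprint, dribbling, ball-control
        times).
    attempts
        Column names holding repeated attempts of the same test.  A variable
        without repeated attempts is stored in a single column named after
        the variable.
    """

    name: str
    orientation: str
    attempts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.orientation not in ("higher", "lower"):
            raise PanelValidationError(
                f"orientation for {self.name!r} must be 'higher' or 'lower', "
                f"got {self.orientation!r}"
            )

    @property
    def columns(self) -> tuple[str, ...]:
        return self.attempts if self.attempts else (self.name,)


@dataclass(frozen=True)
class PanelSchema:
    """Variable declarations for a raw panel."""

    variables: tuple[VariableDecl, ...]
    has_outcome: bool = False

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise PanelValidationError("duplicate variable names in schema")
        cols = self.columns
        if len(set(cols)) != len(cols):
            raise PanelValidationError("duplicate measure columns in schema")

    @property
    def columns(self) -> tuple[str, ...]:
        out: list[str] = []
        for v in self.variables:
            out.extend(v.columns)
        return tuple(out)

    def orientation(self, name: str) -> str:
        for v in self.variables:
            if v.name == name:
                return v.orientation
        raise KeyError(name)

    def variable(self, name: str) -> VariableDecl:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def to_json(self) -> str:
        payload = {
            "has_outcome": self.has_outcome,
            "variables": [
                {
                    "name": v.name,
                    "orientation": v.orientation,
                    **({"attempts": list(v.attempts)} if v.attempts else {}),
                }
                for v in self.variables
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PanelSchema":
        payload = json.loads(text)
        unknown = set(payload) - {"variables", "has_outcome"}
        if unknown:
            raise PanelValidationError(f"unknown schema keys: {sorted(unknown)}")
        decls = []
        for entry in payload["variables"]:
            bad = set(entry) - {"name", "orientation", "attempts"}
            if bad:
                raise PanelValidationError(
                    f"unknown keys in variable declaration: {sorted(bad)}"
                )
            decls.append(
                VariableDecl(
                    name=entry["name"],
                    orientation=entry["orientation"],
                    attempts=tuple(entry.get("attempts", ())),
                )
            )
        return cls(variables=tuple(decls), has_outcome=bool(payload.get("has_outcome", False)))


def _check_long_frame(data: pd.DataFrame, value_cols: Sequence[str]) -> None:
    """Shared person/timepoint validation for raw and factor panels."""
    for col in (PERSON_COL, TIME_COL):
        if col not in data.columns:
            raise PanelValidationError(f"missing required column {col!r}")
    dup = data.duplicated(subset=[PERSON_COL, TIME_COL])
    if dup.any():
        pairs = data.loc[dup, [PERSON_COL, TIME_COL]].values.tolist()
        raise PanelValidationError(f"duplicate (person, timepoint) rows: {pairs}")
    tps = np.sort(data[TIME_COL].unique())
    if len(tps) == 0:
        raise PanelValidationError("panel is empty")
    if not np.array_equal(tps, np.arange(1, len(tps) + 1)):
        raise PanelValidationError(
            f"timepoints must be consecutive integers starting at 1, got {tps.tolist()}"
        )
    for col in value_cols:
        if col not in data.columns:
            raise PanelValidationError(f"missing measure column {col!r}")


@dataclass
class RawPanel:
    """Long-format raw panel: persons x timepoints x declared measure columns.

    ``data`` holds one row per (person, timepoint) with NaN for missing
    cells.  ``outcome`` maps person_id to an ordinal level (0 = lowest); it is
    constant per person and therefore stored once.
    """

    data: pd.DataFrame
    schema: PanelSchema
    outcome: pd.Series | None = None

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        _check_long_frame(self.data, self.schema.columns)
        extra = set(self.data.columns) - {PERSON_COL, TIME_COL} - set(self.schema.columns)
        if extra:
            raise PanelValidationError(f"undeclared measure columns: {sorted(extra)}")
        for col in self.schema.columns:
            try:
                self.data[col] = self.data[col].astype(float)
            except (TypeError, ValueError) as exc:
                raise PanelValidationError(f"non-numeric cell in column {col!r}: {exc}")
        self.data[TIME_COL] = self.data[TIME_COL].astype(int)
        if self.outcome is not None:
            self.outcome = self.outcome.astype(int)
            self.outcome.index.name = PERSON_COL
            missing = set(self.data[PERSON_COL]) - set(self.outcome.index)
            if missing:
                raise PanelValidationError(
                    f"persons without outcome label: {sorted(missing)[:5]} ..."
                )

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.data[TIME_COL].unique().tolist())

    @property
    def persons(self) -> list:
        return sorted(self.data[PERSON_COL].unique().tolist())

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask over the measure columns (True = missing)."""
        return self.data[list(self.schema.columns)].isna()

    def missing_fraction(self) -> float:
        m = self.mask.to_numpy()
        return float(m.sum()) / m.size

    def equals(self, other: "RawPanel") -> bool:
        if self.schema != other.schema:
            return False
        a = self.data.sort_values([PERSON_COL, TIME_COL]).reset_index(drop=True)
        b = other.data.sort_values([PERSON_COL, TIME_COL]).reset_index(drop=True)
        if not a[[PERSON_COL, TIME_COL]].equals(b[[PERSON_COL, TIME_COL]]):
            return False
        va = a[list(self.schema.columns)].to_numpy(float)
        vb = b[list(self.schema.columns)].to_numpy(float)
        if not np.array_equal(np.isnan(va), np.isnan(vb)):
            return False
        if not np.allclose(np.nan_to_num(va), np.nan_to_num(vb), rtol=0, atol=1e-12):
            return False
        if (self.outcome is None) != (other.outcome is None):
            return False
        if self.outcome is not None:
            return self.outcome.sort_index().equals(other.outcome.sort_index())
        return True


@dataclass
class FactorPanel:
    """Persons x timepoints x the four operating factors (no missing values).

    Factor columns follow :data:`FACTOR_NAMES` order.  In the standard
    pipeline the columns are within-timepoint z-scores produced by
    :func:`licur.preprocess.build_factor_panel`; synthetic factor-mode panels
    carry the planted (unstandardized) factor values.
    """

    data: pd.DataFrame
    outcome: pd.Series | None = None

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        _check_long_frame(self.data, FACTOR_NAMES)
        vals = self.data[list(FACTOR_NAMES)]
        if vals.isna().any().any():
            raise PanelValidationError("FactorPanel must be complete (no missing cells)")
        self.data[TIME_COL] = self.data[TIME_COL].astype(int)
        if self.outcome is not None:
            self.outcome = self.outcome.astype(int)
            self.outcome.index.name = PERSON_COL

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.data[TIME_COL].unique().tolist())

    @property
    def persons(self) -> list:
        return sorted(self.data[PERSON_COL].unique().tolist())

    def matrix(self, timepoint: int) -> tuple[list, np.ndarray]:
        """Return (person_ids, n x 4 factor matrix) for one timepoint,
        in sorted person order."""
        sub = self.data[self.data[TIME_COL] == timepoint].sort_values(PERSON_COL)
        if sub.empty:
            raise KeyError(f"no rows at timepoint {timepoint}")
        return sub[PERSON_COL].tolist(), sub[list(FACTOR_NAMES)].to_numpy(float)

    def subset_persons(self, keep: Iterable) -> "FactorPanel":
        keep = set(keep)
        data = self.data[self.data[PERSON_COL].isin(keep)].copy()
        outcome = None
        if self.outcome is not None:
            outcome = self.outcome[self.outcome.index.isin(keep)].copy()
        return FactorPanel(data=data, outcome=outcome)


# ---------------------------------------------------------------------------
# CSV I/O (RFC-4180, UTF-8, '.' decimal separator)
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        encoding="utf-8",
    )
    if frame.empty:
        raise PanelValidationError(f"empty panel file: {path}")
    return frame


def read_panel(path, schema: PanelSchema) -> RawPanel:
    """Read a long-format raw panel from CSV, validating against *schema*."""
    frame = _read_csv(path)
    outcome = None
    if OUTCOME_COL in frame.columns:
        if not schema.has_outcome:
            raise PanelValidationError("outcome column present but schema declares none")
        per_person = frame.groupby(PERSON_COL)[OUTCOME_COL].nunique(dropna=True)
        if (per_person > 1).any():
            bad = per_person[per_person > 1].index.tolist()
            raise PanelValidationError(f"outcome not constant per person: {bad}")
        outcome = (
            frame.dropna(subset=[OUTCOME_COL])
            .groupby(PERSON_COL)[OUTCOME_COL]
            .first()
            .astype(int)
        )
        frame = frame.drop(columns=[OUTCOME_COL])
    elif schema.has_outcome:
        raise PanelValidationError("schema declares an outcome but file has none")
    return RawPanel(data=frame, schema=schema, outcome=outcome)


def write_panel(panel: RawPanel, path) -> None:
    """Write a raw panel to CSV; missing cells become empty fields."""
    frame = panel.data.copy()
    if panel.outcome is not None:
        frame[OUTCOME_COL] = frame[PERSON_COL].map(panel.outcome).astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_factor_panel(path) -> FactorPanel:
    frame = _read_csv(path)
    outcome = None
    if OUTCOME_COL in frame.columns:
        outcome = frame.groupby(PERSON_COL)[OUTCOME_COL].first().astype(int)
        frame = frame.drop(columns=[OUTCOME_COL])
    return FactorPanel(data=frame, outcome=outcome)


def write_factor_panel(panel: FactorPanel, path) -> None:
    frame = panel.data[[PERSON_COL, TIME_COL, *FACTOR_NAMES]].copy()
    if panel.outcome is not None:
        frame[OUTCOME_COL] = frame[PERSON_COL].map(panel.outcome).astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep="", encoding="utf-8")
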