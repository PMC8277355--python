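"""Tidy time-course tables: the common currency of the pipeline.

A :class:`TimeCourseDataset` holds replicate-averaged time courses of one or
more observables under one or more stimulation conditions, together with
their standard errors.  Each (observable, condition) pair is one *series*
``(t_i, y^D_i, sigma_i)``; the calibration objective sums weighted squared
residuals over all series.

Tables are stored and exchanged as plain comma-separated text with the fixed
column contract ``observable, condition, time_s, mean, sem, n,
normalization`` (UTF-8, "." decimal separator).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "NORMALIZATION_MODES",
    "TimeCourseDataset",
    "TimeCourseParseError",
    "MissingColumnError",
    "NonNumericCellError",
    "NonIncreasingTimeError",
    "read_timecourse_table",
    "write_timecourse_table",
]

COLUMNS = ("observable", "condition", "time_s", "mean", "sem", "n", "normalization")
NORMALIZATION_MODES = ("fold_over_basal", "percent_of_max")


class TimeCourseParseError(ValueError):
    """Base class for malformed time-course tables."""


class MissingColumnError(TimeCourseParseError):
    """A required column is absent from the table header."""


class NonNumericCellError(TimeCourseParseError):
    """A numeric column contains a cell that cannot be parsed as a number."""


class NonIncreasingTimeError(TimeCourseParseError):
    """Times within one (observable, condition) series are not strictly increasing."""


@dataclass(frozen=True)
class TimeCourseDataset:
    """Replicate-averaged observable time courses with uncertainties.

    Parameters
    ----------
    frame
        Tidy table with the columns of :data:`COLUMNS`.  One row per
        (observable, condition, time) point.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise MissingColumnError(f"missing required column(s): {missing}")
        frame = self.frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        for col in ("time_s", "mean", "sem"):
            vals = pd.to_numeric(frame[col], errors="coerce")
            bad = vals.isna() & frame[col].notna()
            if bad.any() or frame[col].isna().any():
                raise NonNumericCellError(
                    f"non-numeric or missing value in column {col!r} "
                    f"(first offending row index {int((bad | frame[col].isna()).idxmax())})"
                )
            frame[col] = vals.astype(float)
        n = pd.to_numeric(frame["n"], errors="coerce")
        if n.isna().any():
            raise NonNumericCellError("non-numeric value in column 'n'")
        frame["n"] = n.astype(int)
        if (frame["n"] < 1).any():
            raise TimeCourseParseError("replicate count n must be >= 1")
        if (frame["sem"] < 0).any():
            raise TimeCourseParseError("sem must be non-negative")
        bad_norm = ~frame["normalization"].isin(NORMALIZATION_MODES)
        if bad_norm.any():
            raise TimeCourseParseError(
                f"unknown normalization mode(s): {sorted(frame.loc[bad_norm, 'normalization'].unique())}"
            )
        for (obs, cond), sub in frame.groupby(["observable", "condition"], sort=False):
            t = sub["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise NonIncreasingTimeError(
                    f"times not strictly increasing in series ({obs!r}, {cond!r})"
                )
        object.__setattr__(self, "frame", frame)

    # -- series access -----------------------------------------------------

    @property
    def observables(self) -> list[str]:
        return list(dict.fromkeys(self.frame["observable"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    @property
    def n_series(self) -> int:
        """M: number of (observable, condition) data sets."""
        return int(self.frame.groupby(["observable", "condition"]).ngroups)

    @property
    def n_points(self) -> int:
        return int(len(self.frame))

    def iter_series(self) -> Iterator[tuple[str, str, pd.DataFrame]]:
        for (obs, cond), sub in self.frame.groupby(["observable", "condition"], sort=False):
            yield obs, cond, sub

    def series(self, observable: str, condition: str) -> pd.DataFrame:
        sub = self.frame[
            (self.frame["observable"] == observable) & (self.frame["condition"] == condition)
        ]
        if sub.empty:
            raise KeyError(f"no series ({observable!r}, {condition!r})")
        return sub

    def normalization(self, observable: str) -> str:
        modes = self.frame.loc[self.frame["observable"] == observable, "normalization"].unique()
        if len(modes) != 1:
            raise TimeCourseParseError(
                f"observable {observable!r} has inconsistent normalization modes {list(modes)}"
            )
        return str(modes[0])

    def dynamic_range(self, observable: str) -> float:
        """Spread (max - min) of the observable's means across all conditions."""
        vals = self.frame.loc[self.frame["observable"] == observable, "mean"]
        return float(vals.max() - vals.min())

    # -- provenance --------------------------------------------------------

    def fingerprint(self) -> str:
        """Content hash of the canonical CSV serialization (provenance key)."""
        buf = io.StringIO()
        self._canonical().to_csv(buf, index=False)
        return hashlib.sha256(buf.getvalue().encode("utf-8")).hexdigest()

    def _canonical(self) -> pd.DataFrame:
        return self.frame.sort_values(["observable", "condition", "time_s"]).reset_index(drop=True)

    def equals(self, other: "TimeCourseDataset") -> bool:
        return self._canonical().equals(other._canonical())

    def concat(self, other: "TimeCourseDataset") -> "TimeCourseDataset":
        return TimeCourseDataset(pd.concat([self.frame, other.frame], ignore_index=True))


def write_timecourse_table(dataset: TimeCourseDataset, path: str | Path) -> None:
    """Write the dataset to ``path`` as CSV with the fixed column contract.

    Floats are written with ``repr`` precision so a write→read round trip
    reproduces every value exactly.
    """
    frame = dataset.frame.copy()
    lines = [",".join(COLUMNS)]
    for row in frame.itertuples(index=False):
        lines.append(
            f"{row.observable},{row.condition},{row.time_s!r},{row.mean!r},"
            f"{row.sem!r},{row.n},{row.normalization}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_timecourse_table(path: str | Path) -> TimeCourseDataset:
    """Read a CSV time-course table (see module docstring for the contract)."""
    frame = pd.read_csv(path, dtype={"observable": str, "condition": str, "normalization": str},
                        float_precision="round_trip")
    return TimeCourseDataset(frame)
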