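"""Reading, writing and validating per-animal behavior tables.

The universal input of the pipeline is a :class:`BehaviorTable`: one row
per animal with an opaque ``animal_id``, a ``group`` label, and one
non-negative finite value per configured behavioral measure. Tables are
carried as CSV (UTF-8, header row, dot decimal); values are written at
full precision so a write/read cycle is lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ProfilingConfig
from .errors import ParseError, SchemaError, ValidationError

__all__ = ["BehaviorTable", "read_behavior_table", "write_behavior_table"]

_ID_COLS = ("animal_id", "group")


class BehaviorTable:
    """Validated per-animal table of behavioral measures.

    Parameters
    ----------
    frame
        DataFrame with columns ``animal_id``, ``group`` and one float
        column per measure.
    measures
        Ordered measure-column names. If omitted, every column other
        than the id columns is treated as a measure.
    """

    def __init__(self, frame: pd.DataFrame, measures: Sequence[str] | None = None):
        if measures is None:
            measures = [c for c in frame.columns if c not in _ID_COLS]
        self.measures: tuple[str, ...] = tuple(measures)
        missing = [c for c in (*_ID_COLS, *self.measures) if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = frame.loc[:, [*_ID_COLS, *self.measures]].reset_index(drop=True)
        df["animal_id"] = df["animal_id"].astype(str)
        df["group"] = df["group"].astype(str)
        for m in self.measures:
            df[m] = df[m].astype(float)
        self._frame = df
        self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping],
        measures: Sequence[str] | None = None,
    ) -> "BehaviorTable":
        """Build a table from an iterable of per-animal mappings."""
        df = pd.DataFrame(list(records))
        if df.empty:
            df = pd.DataFrame(columns=[*_ID_COLS, *(measures or ())])
        return cls(df, measures)

    def _validate(self) -> None:
        df = self._frame
        dup = df["animal_id"][df["animal_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(
                f"duplicate animal_id value(s): {', '.join(sorted(set(dup)))}"
            )
        for m in self.measures:
            col = df[m]
            if col.isna().any():
                row = df.loc[col.isna(), "animal_id"].iloc[0]
                raise ValidationError(
                    f"animal {row!r} is missing a value for measure {m!r}"
                )
            if not np.isfinite(col.to_numpy()).all():
                row = df.loc[~np.isfinite(col), "animal_id"].iloc[0]
                raise ValidationError(
                    f"animal {row!r} has a non-finite value for measure {m!r}"
                )
            if (col < 0).any():
                row = df.loc[col < 0, "animal_id"].iloc[0]
                raise ValidationError(
                    f"animal {row!r} has a negative value for measure {m!r}"
                )

    # -- accessors ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BehaviorTable):
            return NotImplemented
        return self.measures == other.measures and self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return (
            f"BehaviorTable({len(self)} animals, "
            f"{len(self.measures)} measures, groups={sorted(self.group_labels)})"
        )

    @property
    def frame(self) -> pd.DataFrame:
        """A defensive copy of the underlying DataFrame."""
        return self._frame.copy()

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Distinct group labels in row order of first appearance."""
        return tuple(dict.fromkeys(self._frame["group"]))

    def group_sizes(self) -> dict[str, int]:
        return self._frame["group"].value_counts().to_dict()

    def for_group(self, group: str) -> "BehaviorTable":
        """Rows belonging to one group, as a new table."""
        return BehaviorTable(
            self._frame[self._frame["group"] == group], self.measures
        )

    def values(self, measure: str) -> np.ndarray:
        if measure not in self.measures:
            raise SchemaError(f"unknown measure {measure!r}")
        return self._frame[measure].to_numpy(copy=True)

    def iter_rows(self):
        """Yield (animal_id, group, {measure: value}) per animal."""
        for rec in self._frame.to_dict("records"):
            vals = {m: rec[m] for m in self.measures}
            yield rec["animal_id"], rec["group"], vals


def read_behavior_table(path, config: ProfilingConfig) -> BehaviorTable:
    """Read and validate a CSV behavior table against a configuration.

    The file must carry a header with ``animal_id``, ``group`` and one
    column per configured measure (order-independent; extra columns are
    ignored). Numbers use dot decimals. Any missing column, unparseable
    cell, missing value, negative/non-finite value or duplicated
    ``animal_id`` raises a specific error naming the offender.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["animal_id", "group", *config.measure_names]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    data = {c: raw[c] for c in _ID_COLS}
    for m in config.measure_names:
        cells = raw[m].str.strip()
        try:
            # element-wise float() is correctly rounded (exact round trip);
            # blank cells become NaN and are rejected by table validation
            numeric = cells.where(cells != "", "nan").astype(float)
        except ValueError:
            for i, cell in enumerate(cells):
                if cell == "":
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path.name}: non-numeric value {raw[m].iloc[i]!r} "
                        f"in column {m!r}, data row {i + 1}"
                    ) from None
            raise
        data[m] = numeric
    return BehaviorTable(pd.DataFrame(data), config.measure_names)


def write_behavior_table(table: BehaviorTable, path) -> None:
    """Write a table as CSV that :func:`read_behavior_table` re-ingests
    losslessly (floats at shortest round-tripping representation)."""
    table._frame.to_csv(path, index=False, lineterminator="\n")
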