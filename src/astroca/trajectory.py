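"""State and trajectory containers plus their CSV/JSON dialects.

A :class:`Trajectory` is a uniform-in-time record of a simulation: a strictly
increasing time grid, one row of state per time point, named columns, and a
``meta`` dictionary recording which model produced it, under which parameters,
seed and solver settings.  Trajectories round-trip through plain CSV
(``t,X,Y,Z[,Gm,Ga]``) with a JSON sidecar for the metadata.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = ["SystemState", "Trajectory", "DEFAULT_INIT"]


@dataclass(frozen=True)
class SystemState:
    """Instantaneous model state.

    X : cytosolic Ca2+ concentration, uM
    Y : endoplasmic-reticulum Ca2+ concentration, uM
    Z : cytosolic IP3 concentration, uM

    In the circuit picture the same triple is read as node voltages
    (V_X, V_Y, V_Z) under the 1 V == 1 uM convention.
    """

    X: float
    Y: float
    Z: float

    def __post_init__(self):
        for name in ("X", "Y", "Z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"state component {name} is not finite: {v!r}")
            if v < 0:
                raise DomainError(f"state component {name} is negative: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z], dtype=float)


#: Default initial condition (uM).  The model's attracting limit cycle makes
#: post-transient statistics insensitive to this choice (verified by the
#: limit-cycle property test).
DEFAULT_INIT = SystemState(0.1, 1.5, 0.1)


@dataclass
class Trajectory:
    """Time series of model states with provenance metadata."""

    times: np.ndarray
    data: np.ndarray
    columns: tuple[str, ...] = ("X", "Y", "Z")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.data.shape[0] != self.times.shape[0]:
            raise ValueError(
                f"states length {self.data.shape[0]} != times length {self.times.shape[0]}"
            )
        if self.data.shape[1] != len(self.columns):
            raise ValueError("data width does not match column names")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        self.columns = tuple(self.columns)

    def __len__(self) -> int:
        return self.times.size

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.columns.index(name)
        except ValueError:
            raise KeyError(f"no column {name!r}; have {self.columns}") from None
        return self.data[:, j]

    def state_at(self, i: int) -> SystemState:
        row = self.data[i]
        return SystemState(row[0], row[1], row[2])

    def with_columns(self, names: tuple[str, ...], values: np.ndarray) -> "Trajectory":
        """Return a copy extended with extra aligned columns (e.g. Gm, Ga)."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] != len(self):
            values = values.T
        return Trajectory(
            times=self.times.copy(),
            data=np.hstack([self.data, values]),
            columns=self.columns + tuple(names),
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.columns))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write ``t,<columns...>`` rows at full float precision."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    def write_meta(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(_jsonable(self.meta), indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, meta: dict | None = None) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0] != "t":
            raise ValueError(f"{path}: first column must be 't', got {df.columns[0]!r}")
        return cls(
            times=df["t"].to_numpy(),
            data=df.iloc[:, 1:].to_numpy(),
            columns=tuple(df.columns[1:]),
            meta=meta or {},
        )


def _jsonable(obj):
    """Best-effort conversion of metadata (dataclasses, arrays) to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if callable(obj):
        return getattr(obj, "__name__", repr(obj))
    return obj
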