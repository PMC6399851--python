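"""Time-gridded simulation output.

A :class:`Trajectory` is a set of named series aligned to a strictly
increasing time grid (days), plus free-form metadata recording the
originating scenario.  It converts to a :class:`pandas.DataFrame` and
round-trips through CSV and JSON records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import GridError, InvalidStateError


@dataclass
class Trajectory:
    """Named value series on a common time grid.

    Parameters
    ----------
    time
        Strictly increasing times in days.
    series
        Mapping of series name to a 1-D array of the grid's length.
    metadata
        Free-form scenario/provenance information (JSON-serialisable).
    """

    time: np.ndarray
    series: dict[str, np.ndarray]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 1:
            raise GridError("time grid must be a non-empty 1-D array")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise GridError("time grid must be strictly increasing")
        clean: dict[str, np.ndarray] = {}
        for name, values in self.series.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.time.shape:
                raise InvalidStateError(
                    f"series {name!r} has length {arr.size}, "
                    f"expected {self.time.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidStateError(f"series {name!r} contains non-finite values")
            clean[name] = arr
        self.series = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def __contains__(self, name: str) -> bool:
        return name in self.series

    def __iter__(self) -> Iterator[str]:
        return iter(self.series)

    @property
    def names(self) -> list[str]:
        return list(self.series)

    def same_grid(self, other: "Trajectory", rtol: float = 1e-12) -> bool:
        return self.time.shape == other.time.shape and np.allclose(
            self.time, other.time, rtol=rtol, atol=1e-12
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_days": self.time}
        data.update(self.series)
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        """Write the trajectory as JSON records (one object per time point)."""
        path = Path(path)
        self.to_frame().to_json(path, orient="records", double_precision=15)
        return path

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, metadata: Mapping[str, Any] | None = None
    ) -> "Trajectory":
        if "time_days" not in frame.columns:
            raise GridError("frame must have a 'time_days' column")
        series = {
            str(c): frame[c].to_numpy(dtype=float)
            for c in frame.columns
            if c != "time_days"
        }
        return cls(
            time=frame["time_days"].to_numpy(dtype=float),
            series=series,
            metadata=dict(metadata or {}),
        )
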