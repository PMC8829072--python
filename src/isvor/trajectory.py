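"""State vectors and time-indexed trajectories.

A :class:`StateVector` holds the five role densities at one instant; a
:class:`Trajectory` is the time-indexed record produced by the mean-field
integrator, a single agent-based run, or an ensemble average.  Baseline
models (SIR/SEIR/Twin-SIR) reuse :class:`Trajectory` with their own column
names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["StateVector", "Trajectory", "ISVOR_COLUMNS"]

ISVOR_COLUMNS: tuple[str, ...] = ("I", "S", "V", "O", "R")


@dataclass(frozen=True)
class StateVector:
    """Densities of the five ISVOR roles; must lie on the unit simplex."""

    I: float
    S: float
    V: float
    O: float
    R: float

    def __post_init__(self) -> None:
        for name in ISVOR_COLUMNS:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"density {name}={v!r} is negative")
        total = self.I + self.S + self.V + self.O + self.R
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"densities sum to {total!r}, expected 1 within 1e-9"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.S, self.V, self.O, self.R], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "StateVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (5,):
            raise ParameterError(f"expected 5 densities, got shape {a.shape}")
        return cls(*a.tolist())

    def __iter__(self) -> Iterator[float]:
        return iter((self.I, self.S, self.V, self.O, self.R))


@dataclass
class Trajectory:
    """Time-indexed densities.

    Attributes
    ----------
    times:
        Strictly increasing time points (continuous time for the ODE,
        integer steps for the agent-based chain).
    data:
        Array of shape ``(len(times), len(columns))`` of densities.
    columns:
        Compartment names, ``("I", "S", "V", "O", "R")`` for ISVOR.
    metadata:
        Free-form provenance: integrator, step size, seed, variant, ...
    stderr:
        Optional pointwise standard errors (same shape as ``data``) for
        ensemble-averaged trajectories.
    """

    times: np.ndarray
    data: np.ndarray
    columns: tuple[str, ...] = ISVOR_COLUMNS
    metadata: dict[str, Any] = field(default_factory=dict)
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.times.shape[0]:
            raise ParameterError(
                f"data shape {self.data.shape} incompatible with "
                f"{self.times.shape[0]} time points"
            )
        if self.data.shape[1] != len(self.columns):
            raise ParameterError(
                f"{self.data.shape[1]} data columns but "
                f"{len(self.columns)} column names"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, name: str) -> np.ndarray:
        """Column access by compartment name."""
        try:
            j = self.columns.index(name)
        except ValueError:
            raise KeyError(name) from None
        return self.data[:, j]

    def state_at(self, i: int) -> StateVector:
        """StateVector at time index ``i`` (ISVOR trajectories only)."""
        if self.columns != ISVOR_COLUMNS:
            raise ParameterError("state_at requires ISVOR columns")
        return StateVector.from_array(self.data[i])

    def final(self) -> dict[str, float]:
        return dict(zip(self.columns, self.data[-1].tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.columns))
        df.insert(0, "t", self.times)
        return df
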