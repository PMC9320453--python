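"""Lightweight containers for per-frame and per-residue scalar observables.

These are deliberately thin: a metric series is a named, unit-carrying pair of
(times, values) arrays, the common currency between the trajectory metrics,
domain geometry and similarity modules and the CSV writers in
:mod:`hingemd.structure_io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, ShapeError

__all__ = ["MetricSeries", "ResidueProfile"]


@dataclass
class MetricSeries:
    """A per-frame scalar observable with units.

    Parameters
    ----------
    metric : str
        Short machine-friendly name, e.g. ``"rmsd"``, ``"rg"``, ``"angle"``.
    values : ndarray, shape (n_frames,)
    times : ndarray, shape (n_frames,)
        Frame times in nanoseconds.
    units : str
        Unit string, e.g. ``"A"`` (angstrom) or ``"deg"``.
    selection : str
        Human-readable description of the atom selection the metric was
        computed on.
    """

    metric: str
    values: np.ndarray
    times: np.ndarray
    units: str = "A"
    selection: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 1 or self.times.ndim != 1:
            raise ShapeError("values and times must be 1-D arrays")
        if len(self.values) != len(self.times):
            raise ShapeError(
                f"length mismatch: {len(self.values)} values vs "
                f"{len(self.times)} times"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in metric series {self.metric!r}")

    def __len__(self) -> int:
        return len(self.values)

    def mean(self, start: int = 0) -> float:
        """Mean of the values from frame index ``start`` onward."""
        if start >= len(self.values):
            raise EmptyInputError("start index beyond end of series")
        return float(np.mean(self.values[start:]))

    def std(self, start: int = 0) -> float:
        """Standard deviation of the values from frame index ``start`` onward."""
        if start >= len(self.values):
            raise EmptyInputError("start index beyond end of series")
        return float(np.std(self.values[start:]))


@dataclass
class ResidueProfile:
    """A per-residue scalar profile (e.g. RMSF), in sequence numbering."""

    residue_numbers: np.ndarray
    values: np.ndarray
    metric: str = "rmsf"
    units: str = "A"
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_numbers) != len(self.values):
            raise ShapeError("one value per residue required")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)
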