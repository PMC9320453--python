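"""The delta-RMSD open/closed progress variable and frame/system state calls.

For a frame at time t, let sigma_closed(t) and sigma_open(t) be the
superposition-fit RMSDs of the frame to a closed and an open reference
structure, each with its own independent fit.  The progress variable is

    delta(t) = sigma_closed(t) - sigma_open(t)

which is negative for closed-like frames, positive for open-like frames and
near zero in between.  Because post-fit RMSD is a metric, |delta(t)| can never
exceed the inter-reference RMSD D, so D sets the natural scale: a frame is
called "intermediate" when |delta| <= threshold_frac * D.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyInputError, ShapeError
from .structure_io import Structure, Trajectory, select
from .superposition import superposed_rmsd

__all__ = [
    "DeltaRmsdSeries",
    "StateCall",
    "delta_rmsd",
    "classify_state",
    "detect_transition",
]

LABELS = ("closed", "intermediate", "open")


@dataclass
class DeltaRmsdSeries:
    """Per-frame sigma_closed, sigma_open and their difference (angstrom)."""

    delta: np.ndarray
    sigma_closed: np.ndarray
    sigma_open: np.ndarray
    times: np.ndarray
    ref_separation: float  # inter-reference post-fit RMSD D, angstrom

    def __post_init__(self) -> None:
        for name in ("delta", "sigma_closed", "sigma_open", "times"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.delta)
        if not (len(self.sigma_closed) == len(self.sigma_open) == len(self.times) == n):
            raise ShapeError("delta, sigmas and times must have equal length")
        if np.any(self.sigma_closed < 0) or np.any(self.sigma_open < 0):
            raise ValueError("RMSD components must be non-negative")
        if not np.allclose(self.delta, self.sigma_closed - self.sigma_open,
                           atol=1e-12):
            raise ValueError("delta must equal sigma_closed - sigma_open")

    def __len__(self) -> int:
        return len(self.delta)

    def swapped(self) -> "DeltaRmsdSeries":
        """The series with the roles of the two references exchanged."""
        return DeltaRmsdSeries(-self.delta, self.sigma_open.copy(),
                               self.sigma_closed.copy(), self.times.copy(),
                               self.ref_separation)


@dataclass
class StateCall:
    """Per-frame and per-system open/closed/intermediate classification."""

    frame_labels: list
    system_label: str
    fractions: dict
    threshold_frac: float
    production_start: int = 0
    extra: dict = field(default_factory=dict)


def delta_rmsd(
    traj: Trajectory,
    ref_closed: Structure | np.ndarray,
    ref_open: Structure | np.ndarray,
    indices: np.ndarray | None = None,
) -> DeltaRmsdSeries:
    """Compute the delta-RMSD progress variable for every frame.

    Each sigma is a post-fit RMSD with its own independent superposition of
    the frame onto the respective reference over ``indices`` (default: all
    C-alpha atoms).
    """
    closed = ref_closed.coords if isinstance(ref_closed, Structure) else np.asarray(ref_closed, float)
    open_ = ref_open.coords if isinstance(ref_open, Structure) else np.asarray(ref_open, float)
    if closed.shape != (traj.n_atoms, 3) or open_.shape != (traj.n_atoms, 3):
        raise ShapeError(
            "reference structures must match the trajectory topology "
            f"({traj.n_atoms} atoms)"
        )
    if indices is None:
        indices = select(traj, "CA")
    indices = np.asarray(indices, dtype=int)

    sigma_c = np.array([
        superposed_rmsd(traj.frames[i], closed, indices) for i in range(traj.n_frames)
    ])
    sigma_o = np.array([
        superposed_rmsd(traj.frames[i], open_, indices) for i in range(traj.n_frames)
    ])
    d_ref = superposed_rmsd(closed, open_, indices)
    return DeltaRmsdSeries(sigma_c - sigma_o, sigma_c, sigma_o,
                           traj.times, d_ref)


def classify_state(
    series: DeltaRmsdSeries,
    threshold_frac: float = 0.2,
    production_start: int = 0,
) -> StateCall:
    """Label frames closed / intermediate / open and call the system state.

    A frame is ``closed`` if delta < -threshold_frac * D, ``open`` if
    delta > +threshold_frac * D, otherwise ``intermediate`` (D being the
    inter-reference RMSD).  The per-system label is the majority label over
    the production run (frames from ``production_start`` on); per-label
    fractions are reported alongside.
    """
    D = series.ref_separation
    if D <= 1e-10:  # identical references up to superposition
        raise ConfigError(
            "identical closed/open references (D = 0): state undefined"
        )
    if threshold_frac < 0:
        raise ConfigError("threshold_frac must be non-negative")
    if production_start >= len(series):
        raise EmptyInputError("production_start beyond end of series")
    cut = threshold_frac * D
    labels = np.full(len(series), "intermediate", dtype=object)
    labels[series.delta < -cut] = "closed"
    labels[series.delta > cut] = "open"
    prod = labels[production_start:]
    counts = Counter(prod)
    fractions = {lab: counts.get(lab, 0) / len(prod) for lab in LABELS}
    # deterministic tie-break: closed < intermediate < open by LABELS order
    system = max(LABELS, key=lambda lab: (fractions[lab], -LABELS.index(lab)))
    return StateCall(list(labels), system, fractions, threshold_frac,
                     production_start)


def detect_transition(
    series: DeltaRmsdSeries,
    baseline_frames: int = 50,
    n_sigma: float = 6.0,
    sustain: int = 3,
    min_jump: float = 0.0,
) -> int | None:
    """First frame at which delta departs from its initial baseline.

    The baseline mean and standard deviation are estimated on the first
    ``baseline_frames`` frames; the detected transition is the first frame
    where |delta - mean| exceeds ``max(n_sigma * std, min_jump)`` for
    ``sustain`` consecutive frames.  Returns None when no such departure
    occurs (a run that stays in its starting basin).
    """
    n = len(series)
    if baseline_frames < 2 or baseline_frames >= n:
        raise ConfigError("baseline_frames must be in [2, n_frames)")
    base = series.delta[:baseline_frames]
    mean, std = float(np.mean(base)), float(np.std(base))
    cut = max(n_sigma * std, min_jump, 1e-12)
    outside = np.abs(series.delta - mean) > cut
    run = 0
    for i in range(baseline_frames, n):
        run = run + 1 if outside[i] else 0
        if run >= sustain:
            return i - sustain + 1
    return None
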