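"""Per-frame RMSD, per-residue RMSF, and equilibration-point estimation.

All deviations are computed on coordinates after rigid-body superposition
(:mod:`hingemd.superposition`).  RMSD follows

    RMSD(t) = sqrt( (1/N) sum_i |r_i(t) - r_i_ref|^2 )

over the measured selection.  RMSF is computed about the trajectory-average
structure: frames are first aligned to the first frame, the mean structure is
taken, the trajectory is re-aligned to that mean, and

    RMSF(i) = sqrt( (1/T) sum_t |r_i(t) - <r_i>|^2 ).

The equilibration point of a metric series is the end of the earliest window
from which every subsequent window is statistically flat (small linear slope,
window means within twice the pooled standard deviation); frames after that
point constitute the production run.
"""
from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateGeometryError, EmptyInputError, ShapeError
from .series import MetricSeries, ResidueProfile
from .structure_io import DomainSet, Structure, Trajectory, select
from .superposition import kabsch_superpose, superposed_rmsd

__all__ = [
    "MetricSeries",
    "ResidueProfile",
    "rmsd_series",
    "per_domain_rmsd",
    "rmsf_profile",
    "estimate_equilibration",
    "NOT_EQUILIBRATED",
]

#: Sentinel returned by estimate_equilibration when no window qualifies.
NOT_EQUILIBRATED = None


def _resolve_indices(traj: Trajectory, indices, default_spec="CA",
                     domains: DomainSet | None = None) -> np.ndarray:
    if indices is None:
        return select(traj, default_spec, domains)
    return np.asarray(indices, dtype=int)


def rmsd_series(
    traj: Trajectory,
    reference: Structure | np.ndarray | None = None,
    fit_indices: np.ndarray | None = None,
    measure_indices: np.ndarray | None = None,
    selection_label: str = "",
    strict: bool = False,
) -> MetricSeries:
    """Per-frame RMSD (angstrom) of a trajectory against a reference.

    Each frame is superposed onto the reference over ``fit_indices`` and the
    RMSD is then measured over ``measure_indices`` (defaulting to the fit
    selection).  ``reference`` defaults to the first frame.

    ``strict=False`` (default) accepts degenerate fit selections (e.g. a
    two-atom system), for which the minimum RMSD value is still well
    defined; ``strict=True`` raises for them instead.
    """
    if reference is None:
        ref_coords = traj.frames[0]
    elif isinstance(reference, Structure):
        ref_coords = reference.coords
    else:
        ref_coords = np.asarray(reference, dtype=float)
    if ref_coords.shape != (traj.n_atoms, 3):
        raise ShapeError(
            f"reference has {ref_coords.shape} coords, topology expects "
            f"{(traj.n_atoms, 3)}"
        )
    values = np.array([
        superposed_rmsd(traj.frames[i], ref_coords, fit_indices,
                        measure_indices, strict=strict)
        for i in range(traj.n_frames)
    ])
    return MetricSeries("rmsd", values, traj.times, units="A",
                        selection=selection_label)


def per_domain_rmsd(
    traj: Trajectory,
    reference: Structure | np.ndarray | None,
    domains: DomainSet,
    atom_name: str = "CA",
) -> dict[str, MetricSeries]:
    """Per-domain RMSD with an independent superposition per domain.

    For each domain, the fit and the measurement both use only that domain's
    atoms (of ``atom_name``), so rigid-body motion of a whole domain does not
    register — the series tracks internal domain deformation only.
    """
    out: dict[str, MetricSeries] = {}
    for name in domains.names():
        idx = select(traj, f"{atom_name} and domain {name}", domains)
        if len(idx) < 3:
            raise DegenerateGeometryError(
                f"domain {name!r} resolves to {len(idx)} {atom_name} atoms; "
                "need at least 3 for superposition"
            )
        out[name] = rmsd_series(traj, reference, fit_indices=idx,
                                measure_indices=idx,
                                selection_label=f"{atom_name} and domain {name}")
    return out


def _align_all(frames: np.ndarray, reference: np.ndarray,
               fit_indices: np.ndarray) -> np.ndarray:
    aligned = np.empty_like(frames)
    for i in range(frames.shape[0]):
        _, aligned[i] = kabsch_superpose(frames[i], reference, fit_indices)
    return aligned


def rmsf_profile(
    traj: Trajectory,
    measure_indices: np.ndarray | None = None,
    fit_indices: np.ndarray | None = None,
    domains: DomainSet | None = None,
    single_frame: str = "warn",
) -> ResidueProfile:
    """Per-residue RMSF (angstrom) about the trajectory-average structure.

    Procedure: align every frame to the first frame over ``fit_indices``
    (defaulting to the measured selection), average the aligned coordinates,
    re-align the trajectory to that average, and take the per-atom RMS
    deviation about it.  One value is reported per measured atom
    (conventionally the C-alpha of each residue), keyed by sequence residue
    number (the DomainSet offset, when given, is subtracted from file
    numbering).

    ``single_frame``: ``"warn"`` returns an all-zero profile with a recorded
    warning for a 1-frame trajectory; ``"error"`` raises instead.
    """
    idx = _resolve_indices(traj, measure_indices, "CA", domains)
    fit = idx if fit_indices is None else np.asarray(fit_indices, dtype=int)
    offset = domains.offset if domains is not None else 0
    res_numbers = traj.topology.residue_numbers[idx] - offset
    if traj.n_frames < 2:
        msg = "RMSF of a single-frame trajectory is identically zero"
        if single_frame == "error":
            raise EmptyInputError(msg)
        warnings.warn(msg, stacklevel=2)
        return ResidueProfile(res_numbers, np.zeros(len(idx)), warnings=[msg])

    aligned = _align_all(traj.frames, traj.frames[0], fit)
    mean_structure = aligned.mean(axis=0)
    aligned = _align_all(aligned, mean_structure, fit)
    mean_structure = aligned.mean(axis=0)
    sq_dev = np.sum((aligned[:, idx, :] - mean_structure[idx]) ** 2, axis=-1)
    values = np.sqrt(sq_dev.mean(axis=0))
    return ResidueProfile(res_numbers, values)


def estimate_equilibration(
    series: MetricSeries,
    window: int | None = None,
    slope_tol: float = 0.02,
) -> float | None:
    """Estimate the equilibration time of a metric series.

    Scans candidate start frames; a start qualifies when, partitioning the
    remaining frames into consecutive windows of ``window`` frames, every
    window's least-squares linear slope satisfies ``|slope| <= slope_tol``
    (in units of the metric per ns) and the spread of window means does not
    exceed twice the pooled within-window standard deviation.  The
    equilibration point is the end of the first window of the earliest
    qualifying start; frames after it are the production run.

    Parameters
    ----------
    window : int, optional
        Window length in frames; defaults to 10% of the series (minimum 4).
    slope_tol : float
        Maximum tolerated |slope|, metric units per ns (default 0.02).

    Returns
    -------
    float or None
        Equilibration time in ns, or :data:`NOT_EQUILIBRATED` (None) when no
        start qualifies (e.g. a monotone drift).
    """
    n = len(series)
    if window is None:
        window = max(4, n // 10)
    if n < 2 * window:
        raise EmptyInputError(
            f"series of {n} frames is too short for window={window} "
            "(need at least 2 windows)"
        )
    times = series.times
    values = series.values
    step = max(1, window // 10)

    for start in range(0, n - 2 * window + 1, step):
        ok = True
        means, variances = [], []
        for w0 in range(start, n - window + 1, window):
            tw = times[w0:w0 + window]
            vw = values[w0:w0 + window]
            slope = np.polyfit(tw, vw, 1)[0]
            if abs(slope) > slope_tol:
                ok = False
                break
            means.append(vw.mean())
            variances.append(vw.var(ddof=1))
        if not ok:
            continue
        pooled_std = float(np.sqrt(np.mean(variances)))
        if (max(means) - min(means)) > 2.0 * pooled_std:
            continue
        eq_index = min(start + window, n - 1)
        return float(times[eq_index])
    return NOT_EQUILIBRATED


def production_start_index(series: MetricSeries, t_eq_ns: float | None) -> int:
    """First frame index of the production run given an equilibration time."""
    if t_eq_ns is None:
        return 0
    return int(np.searchsorted(series.times, t_eq_ns))
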