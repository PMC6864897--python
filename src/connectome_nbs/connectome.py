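"""Functional connectome construction and structural-matrix ingestion.

Functional pipeline (fixed order): frame-wise displacement QC -> scrubbing
with B-spline interpolation -> nuisance regression -> temporal filtering ->
pairwise Pearson correlation. Structural streamline-count matrices are
validated and symmetrized on ingestion.

Frame-wise displacement follows the standard convention: the sum of absolute
frame-to-frame changes of the three translations (mm) plus the three
rotations converted to arc length on a 50 mm sphere. Frames with FD strictly
above 0.5 mm are flagged; subjects with more than 10% flagged frames are
excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal
from scipy.interpolate import make_interp_spline

from .datatypes import (
    ConnectivityMatrix,
    FDSeries,
    SubjectExcludedError,
    TimeSeriesBundle,
)

__all__ = [
    "compute_fd",
    "scrub_and_interpolate",
    "regress_nuisance",
    "temporal_filter",
    "pearson_connectome",
    "ingest_structural",
    "build_functional_connectome",
    "FD_THRESHOLD_MM",
    "MAX_FLAGGED_FRACTION",
    "HEAD_RADIUS_MM",
]

FD_THRESHOLD_MM = 0.5
MAX_FLAGGED_FRACTION = 0.10
HEAD_RADIUS_MM = 50.0


def compute_fd(
    motion: np.ndarray,
    threshold: float = FD_THRESHOLD_MM,
    head_radius: float = HEAD_RADIUS_MM,
    rotations_in_degrees: bool = False,
) -> FDSeries:
    """Frame-wise displacement from a frames x 6 motion-parameter table.

    ``fd[t] = sum_i |d trans_i| + sum_j r * |d rot_j|`` with ``fd[0] = 0``.
    Rotations are radians unless ``rotations_in_degrees`` is set (the
    degrees-vs-radians contract is the caller's).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion must have 6 columns (3 translations mm, 3 rotations), "
            f"got shape {motion.shape}")
    rot = motion[:, 3:]
    if rotations_in_degrees:
        rot = np.deg2rad(rot)
    dtrans = np.abs(np.diff(motion[:, :3], axis=0)).sum(axis=1)
    drot = np.abs(np.diff(rot, axis=0)).sum(axis=1) * head_radius
    fd = np.concatenate([[0.0], dtrans + drot])
    return FDSeries(fd=fd, flagged=fd > threshold, threshold=threshold)


def scrub_and_interpolate(
    bundle: TimeSeriesBundle,
    fd: FDSeries,
    max_flagged_fraction: float = MAX_FLAGGED_FRACTION,
    spline_order: int = 3,
) -> TimeSeriesBundle:
    """Replace high-motion frames by B-spline interpolation per node.

    Flagged frames are rebuilt, node by node, from a spline (cubic by
    default) fit through the unflagged frame indices; unflagged frames are
    untouched. Flagged frames at the sequence boundary, where interpolation
    would extrapolate, are clamped to the nearest valid frame with a warning.

    Raises
    ------
    SubjectExcludedError
        If the flagged fraction exceeds ``max_flagged_fraction`` (default
        10%), signalling that the subject must be dropped from analysis.
    """
    if fd.fd.shape[0] != bundle.n_frames:
        raise ValueError("FD series not aligned to bundle frames")
    flagged = fd.flagged
    frac = fd.flagged_fraction
    if frac > max_flagged_fraction:
        raise SubjectExcludedError(
            f"subject {bundle.subject_id!r}: {frac:.1%} frames exceed "
            f"FD {fd.threshold} mm (limit {max_flagged_fraction:.0%})")
    if not flagged.any():
        return bundle.replace_signals(bundle.signals.copy())

    good = np.nonzero(~flagged)[0]
    bad = np.nonzero(flagged)[0]
    order = min(spline_order, len(good) - 1)
    sig = bundle.signals.copy()
    lo, hi = good[0], good[-1]
    interior = bad[(bad > lo) & (bad < hi)]
    boundary = bad[(bad < lo) | (bad > hi)]
    if interior.size:
        spline = make_interp_spline(good, bundle.signals[good], k=order,
                                    axis=0)
        sig[interior] = spline(interior)
    if boundary.size:
        warnings.warn(
            f"{boundary.size} flagged frame(s) at the sequence boundary; "
            "using nearest-valid-frame values", RuntimeWarning,
            stacklevel=2)
        for t in boundary:
            sig[t] = bundle.signals[lo if t < lo else hi]
    return bundle.replace_signals(sig)


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns beyond the numerical rank (QR with pivoting)."""
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(x)
    _, _, piv = qr(x, pivoting=True, mode="economic")
    return [names[i] for i in sorted(piv[rank:])]


def regress_nuisance(
    bundle: TimeSeriesBundle, include_motion: bool = True
) -> TimeSeriesBundle:
    """Residualize every node signal on the nuisance set.

    The regression design is [intercept | WM | CSF | (task) | 6 motion
    parameters]; each node signal is replaced by its OLS residual, which is
    numerically orthogonal to every nuisance column. Task-condition
    regressors are only admissible for active-task modalities.
    ``include_motion=False`` drops the motion block (e.g. when the trace is
    degenerate or motion was handled elsewhere).
    """
    task_cols = [n for n in bundle.nuisance_names if "task" in n.lower()]
    if bundle.modality == "rest" and task_cols:
        raise ValueError(
            f"task regressors {task_cols} supplied for resting-state data; "
            "task-condition regression applies to active tasks only")
    n = bundle.n_frames
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if bundle.nuisance.size:
        parts.append(bundle.nuisance)
        names.extend(bundle.nuisance_names)
    if include_motion:
        parts.append(bundle.motion)
        names.extend([f"motion_{i}" for i in range(1, 7)])
    x = np.hstack(parts)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, names)
        raise ValueError(f"nuisance design is rank deficient; collinear "
                         f"columns: {bad}")
    return bundle.replace_signals(_ols_residuals(bundle.signals, x))


def _dct_highpass_basis(n_frames: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis for frequencies below 1/cutoff Hz."""
    order = int(np.floor(2.0 * n_frames * tr / cutoff_s))
    t = np.arange(n_frames)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_frames))
            for k in range(1, order + 1)]
    if not cols:
        return np.empty((n_frames, 0))
    return np.column_stack(cols)


def temporal_filter(
    bundle: TimeSeriesBundle,
    band_hz: tuple[float, float] = (0.008, 0.1),
    highpass_cutoff_s: float = 128.0,
) -> TimeSeriesBundle:
    """Temporal filtering keyed by modality.

    Resting-state data get a zero-phase band-pass (second-order Butterworth
    run forward and backward, 0.008-0.1 Hz); active-task data are high-pass
    filtered by regressing out a discrete-cosine drift basis with a 128 s
    cutoff (plus the mean).
    """
    fs = 1.0 / bundle.sampling_interval
    sig = bundle.signals
    if bundle.modality == "rest":
        lo, hi = band_hz
        nyq = fs / 2.0
        if hi >= nyq:
            raise ValueError(f"band edge {hi} Hz exceeds Nyquist {nyq} Hz")
        sos = sp_signal.butter(2, [lo, hi], btype="bandpass", fs=fs,
                               output="sos")
        padlen = 3 * (2 * 2 + 1)  # sosfiltfilt default for a 2nd-order section pair
        if bundle.n_frames <= padlen:
            raise ValueError(
                f"{bundle.n_frames} frames too short for the band-pass "
                f"filter (need > {padlen})")
        filtered = sp_signal.sosfiltfilt(sos, sig, axis=0)
    else:
        basis = _dct_highpass_basis(bundle.n_frames,
                                    bundle.sampling_interval,
                                    highpass_cutoff_s)
        x = np.hstack([np.ones((bundle.n_frames, 1)), basis])
        if x.shape[1] >= bundle.n_frames:
            raise ValueError("too few frames for the high-pass drift basis")
        filtered = _ols_residuals(sig, x)
    return bundle.replace_signals(np.ascontiguousarray(filtered))


def pearson_connectome(
    bundle: TimeSeriesBundle,
    qc_log: list | None = None,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlations between all node signals.

    Zero-variance nodes cannot be correlated; their edges are set to 0 and
    the node indices are appended to ``qc_log`` (and warned about).
    """
    sig = bundle.signals
    sd = sig.std(axis=0)
    # relative tolerance: a constant signal's std is float-rounding noise
    dead = np.nonzero(sd <= 1e-12 * (1.0 + np.abs(sig).max(axis=0)))[0]
    if dead.size:
        warnings.warn(
            f"subject {bundle.subject_id!r}: zero-variance node(s) "
            f"{dead.tolist()}; their edges are set to 0", RuntimeWarning,
            stacklevel=2)
        if qc_log is not None:
            qc_log.extend(int(i) for i in dead)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sig, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)  # zero-variance rows produce NaN
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    if dead.size:
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(weights=r, modality="functional",
                              subject_id=bundle.subject_id)


def ingest_structural(
    matrix: np.ndarray,
    subject_id: str = "",
    asymmetry_tolerance: float = 0.0,
    qc_log: list | None = None,
) -> ConnectivityMatrix:
    """Validate a streamline-count matrix and coerce it to canonical form.

    Counts must be nonnegative integers in a square matrix. Tracking outputs
    may be asymmetric or upper-triangle-only; the two triangles are merged by
    element-wise max (streamline counts are direction-agnostic). Asymmetry
    beyond ``asymmetry_tolerance`` is recorded in ``qc_log``.
    """
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"structural matrix must be square, got {w.shape}")
    if np.any(w < 0):
        raise ValueError("structural matrix contains negative counts")
    if not np.allclose(w, np.round(w)):
        raise ValueError("structural matrix contains non-integer entries")
    asym = np.abs(w - w.T).max()
    if asym > asymmetry_tolerance and qc_log is not None:
        qc_log.append(
            f"subject {subject_id!r}: max triangle asymmetry {asym:g}")
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w, modality="structural",
                              subject_id=subject_id)


def build_functional_connectome(
    bundle: TimeSeriesBundle,
    fd_threshold: float = FD_THRESHOLD_MM,
    max_flagged_fraction: float = MAX_FLAGGED_FRACTION,
    rotations_in_degrees: bool = False,
    qc_log: list | None = None,
) -> tuple[ConnectivityMatrix, FDSeries]:
    """Full per-subject functional pipeline.

    Composes FD computation, scrubbing + interpolation, nuisance regression,
    modality-appropriate temporal filtering and Pearson correlation, in that
    fixed order. Returns the connectivity matrix and the FD series (for QC
    reporting). Raises :class:`SubjectExcludedError` when motion QC fails.
    """
    fd = compute_fd(bundle.motion, threshold=fd_threshold,
                    rotations_in_degrees=rotations_in_degrees)
    cleaned = scrub_and_interpolate(bundle, fd,
                                    max_flagged_fraction=max_flagged_fraction)
    cleaned = regress_nuisance(cleaned)
    cleaned = temporal_filter(cleaned)
    return pearson_connectome(cleaned, qc_log=qc_log), fd
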