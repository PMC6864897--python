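"""Core in-memory containers shared across the pipeline.

The pipeline operates on region-level ("node") data: per-subject node x frame
signal matrices with their motion and nuisance traces, per-subject node x node
connectivity matrices (Pearson r for functional data, streamline counts for
structural data), and a cohort-level design table carrying group labels,
covariates and behavioral scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesBundle",
    "FDSeries",
    "ConnectivityMatrix",
    "CohortDesign",
    "MODALITIES",
    "SubjectExcludedError",
]

#: functional acquisition tags; "structural" marks streamline-count matrices
MODALITIES = ("faces", "nback", "rest")

#: design-table columns that must always be present
DESIGN_REQUIRED = ("subject_id", "group", "age", "sex", "site", "protocol")

#: optional behavioral score columns
BEHAVIORAL_COLUMNS = ("erq_reappraisal", "erq_suppression", "srrs")


class SubjectExcludedError(RuntimeError):
    """Raised when a subject fails a quality-control criterion (e.g. more
    than the tolerated fraction of high-motion frames)."""


@dataclass
class TimeSeriesBundle:
    """One subject's node time series plus the traces needed to denoise it.

    Parameters
    ----------
    signals
        ``(n_frames, n_nodes)`` array of mean regional signals.
    motion
        ``(n_frames, 6)`` rigid-body realignment parameters: three
        translations in mm followed by three rotations in radians.
    nuisance
        ``(n_frames, k)`` nuisance regressors (white-matter signal, CSF
        signal, optional task-condition regressors). Motion columns are kept
        separately in ``motion`` and joined at regression time.
    nuisance_names
        Column names for ``nuisance``; task regressors must contain ``task``
        in their name so the modality contract can be enforced.
    sampling_interval
        Seconds per frame (TR).
    modality
        One of ``{"faces", "nback", "rest"}``.
    """

    signals: np.ndarray
    motion: np.ndarray
    nuisance: np.ndarray
    nuisance_names: list[str]
    sampling_interval: float
    modality: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.nuisance = np.asarray(self.nuisance, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a frames x nodes matrix")
        n = self.n_frames
        if n < 8:
            raise ValueError(f"need at least 8 frames, got {n}")
        if self.motion.shape != (n, 6):
            raise ValueError(
                f"motion must be ({n}, 6), got {self.motion.shape}"
            )
        if self.nuisance.size and self.nuisance.shape[0] != n:
            raise ValueError("nuisance rows must match signal frames")
        if self.nuisance.size and self.nuisance.shape[1] != len(self.nuisance_names):
            raise ValueError("nuisance_names must match nuisance columns")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        for name, arr in (("signals", self.signals), ("motion", self.motion),
                          ("nuisance", self.nuisance)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.signals.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.signals.shape[1]

    def replace_signals(self, signals: np.ndarray) -> "TimeSeriesBundle":
        """Return a copy of the bundle with new signal values."""
        return TimeSeriesBundle(
            signals=signals,
            motion=self.motion,
            nuisance=self.nuisance,
            nuisance_names=list(self.nuisance_names),
            sampling_interval=self.sampling_interval,
            modality=self.modality,
            subject_id=self.subject_id,
        )


@dataclass
class FDSeries:
    """Per-frame frame-wise displacement (mm) and the high-motion flags."""

    fd: np.ndarray
    flagged: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.fd.shape != self.flagged.shape:
            raise ValueError("fd and flagged must align")
        if np.any(self.fd < 0):
            raise ValueError("FD is nonnegative by construction")
        if not np.array_equal(self.flagged, self.fd > self.threshold):
            raise ValueError("flagged must equal fd > threshold (strict)")

    @property
    def flagged_fraction(self) -> float:
        return float(np.mean(self.flagged))


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node edge-weight matrix with a modality tag.

    Functional weights are Pearson correlations in [-1, 1]; structural
    weights are nonnegative integer streamline counts. The diagonal carries
    no information and is stored as 0.
    """

    weights: np.ndarray
    modality: str  # "functional" | "structural"
    subject_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        if self.modality == "functional":
            if np.any(np.abs(w) > 1 + 1e-12):
                raise ValueError("functional weights must lie in [-1, 1]")
            w = np.clip(w, -1.0, 1.0)
        elif self.modality == "structural":
            if np.any(w < 0):
                raise ValueError("structural weights must be nonnegative")
            if not np.allclose(w, np.round(w)):
                raise ValueError("structural weights must be integer counts")
        else:
            raise ValueError("modality must be 'functional' or 'structural'")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class CohortDesign:
    """Subject-level design table: group factor, covariates, behavioral scores.

    ``group`` is a binary factor with levels ``"H"`` (high expression) and
    ``"L"`` (low expression); ``sex`` is coded ``"M"``/``"F"``; ``site`` and
    ``protocol`` are unordered factors. Behavioral columns
    (``erq_reappraisal``, ``erq_suppression``, ``srrs``) are optional and may
    contain missing values.
    """

    table: pd.DataFrame
    group_levels: tuple[str, str] = ("H", "L")

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in design table")
        levels = set(self.table["group"].unique())
        if not levels.issubset(set(self.group_levels)):
            raise ValueError(
                f"group levels {levels} not in {self.group_levels}"
            )
        if len(levels) < 2:
            raise ValueError("both group levels must be present")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    def group_indicator(self) -> np.ndarray:
        """0/1 indicator of the low-expression group (1 = L)."""
        return (self.table["group"] == self.group_levels[1]).to_numpy(float)

    def covariate_matrix(
        self, covariates: tuple[str, ...] = ("age", "sex", "site", "protocol")
    ) -> tuple[np.ndarray, list[str]]:
        """Full-rank dummy-coded covariate matrix (no intercept column).

        Numeric columns pass through; factors are expanded to k-1 dummies.
        """
        blocks: list[np.ndarray] = []
        names: list[str] = []
        for cov in covariates:
            col = self.table[cov]
            if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
                blocks.append(col.to_numpy(float)[:, None])
                names.append(cov)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=cov,
                                         drop_first=True)
                if dummies.shape[1]:
                    blocks.append(dummies.to_numpy(float))
                    names.extend(dummies.columns)
        if not blocks:
            return np.empty((len(self), 0)), []
        return np.hstack(blocks), names

    def subset(self, mask: np.ndarray) -> "CohortDesign":
        sub = self.table.loc[np.asarray(mask, bool)].reset_index(drop=True)
        return CohortDesign(sub, self.group_levels)
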