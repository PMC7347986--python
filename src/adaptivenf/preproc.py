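"""Motion quantification, TR censoring, nuisance regressors, and normalization.

Framewise displacement (FD) is the sum of absolute temporal differences of the
six rigid-body parameters; rotations are converted to millimetres of arc on a
50 mm sphere by default (the Power convention), with a raw-sum mode available
since summing raw parameter differences is also a defensible reading of the
measure. Censoring removes TRs with FD above threshold plus the immediately
following TR, then isolated kept TRs, and drops whole runs that lose half or
more of their TRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class MotionTrace:
    """TR x 6 rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    values: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 6:
            raise ValueError(f"motion trace must be TR x 6, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("motion trace contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FDTrace:
    """Per-TR framewise displacement in mm; the first entry is defined 0."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("FD values must be non-negative")
        object.__setattr__(self, "values", v)


class CensorReason(Enum):
    KEPT = "kept"
    FD_SPIKE = "fd_spike"
    POST_SPIKE = "post_spike"
    ISOLATED = "isolated"
    RUN_DROPPED = "run_dropped"


@dataclass(frozen=True)
class CensorMask:
    """Boolean keep vector per TR with a reason code for each censored TR."""

    keep: np.ndarray
    reasons: np.ndarray  # array of CensorReason

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    def to_lines(self) -> str:
        """Serialize as one 0/1 per line (1 = keep), the common censor-file form."""
        return "\n".join("1" if k else "0" for k in self.keep) + "\n"

    @classmethod
    def from_lines(cls, text: str) -> "CensorMask":
        keep = np.array([bool(int(line)) for line in text.split()], dtype=bool)
        reasons = np.where(keep, CensorReason.KEPT, CensorReason.FD_SPIKE)
        return cls(keep=keep, reasons=reasons)


def framewise_displacement(
    motion: MotionTrace, rotation_radius_mm: float | None = 50.0
) -> FDTrace:
    """FD_t = sum over the six parameters of |R_{t,i} - R_{t-1,i}|; FD_1 = 0.

    Rotation columns (degrees) are converted to mm of arc length on a sphere
    of ``rotation_radius_mm`` (default 50 mm); pass ``None`` to sum raw
    parameter differences without unit conversion.
    """
    v = motion.values
    if v.shape[0] < 2:
        raise ValueError("need at least 2 TRs to compute FD")
    scaled = v.copy()
    if rotation_radius_mm is not None:
        scaled[:, 3:] = np.deg2rad(scaled[:, 3:]) * rotation_radius_mm
    fd = np.zeros(v.shape[0])
    fd[1:] = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return FDTrace(values=fd)


def censor_mask(
    fd: FDTrace, threshold_mm: float = 0.4, run_drop_fraction: float = 0.5
) -> CensorMask:
    """Build the TR censor mask from an FD trace.

    TRs with FD above ``threshold_mm`` are censored together with the
    immediately following TR; kept TRs whose preceding and following TRs are
    both censored are then censored as isolated (a boundary TR has no
    preceding/following TR, so it can never be isolated); finally, if the
    censored fraction reaches ``run_drop_fraction`` the whole run is
    censored.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    v = fd.values
    n = len(v)
    keep = np.ones(n, dtype=bool)
    reasons = np.full(n, CensorReason.KEPT, dtype=object)

    spikes = v > threshold_mm
    keep[spikes] = False
    reasons[spikes] = CensorReason.FD_SPIKE
    post = np.zeros(n, dtype=bool)
    post[1:] = spikes[:-1]
    post &= keep  # do not overwrite a spike's own code
    keep[post] = False
    reasons[post] = CensorReason.POST_SPIKE

    # isolated sweep: requires an existing censored neighbour on both sides
    padded = np.concatenate([[True], keep, [True]])
    isolated = padded[1:-1] & ~padded[:-2] & ~padded[2:]
    keep[isolated] = False
    reasons[isolated] = CensorReason.ISOLATED

    if n > 0 and (~keep).sum() / n >= run_drop_fraction:
        reasons[keep] = CensorReason.RUN_DROPPED
        keep[:] = False

    return CensorMask(keep=keep, reasons=reasons)


def volterra_nuisance(
    motion: MotionTrace, csf: np.ndarray, wm: np.ndarray
) -> "NuisanceMatrix":
    """26-column nuisance set: [R R^2 R_{t-1} R^2_{t-1}] plus CSF and WM means.

    The lagged columns are zero-padded at the first row.
    """
    R = motion.values
    n = R.shape[0]
    csf = np.asarray(csf, dtype=float)
    wm = np.asarray(wm, dtype=float)
    if len(csf) != n or len(wm) != n:
        raise ValueError(
            f"csf/wm lengths ({len(csf)}, {len(wm)}) do not match TR count {n}"
        )
    R2 = R**2
    lag = np.zeros_like(R)
    lag[1:] = R[:-1]
    lag2 = np.zeros_like(R)
    lag2[1:] = R2[:-1]
    cols = np.column_stack([R, R2, lag, lag2, csf, wm])
    motion_names = [f"{kind}{i+1}" for kind in ("trans", "rot") for i in range(3)]
    names = (
        motion_names
        + [f"{m}_sq" for m in motion_names]
        + [f"{m}_lag" for m in motion_names]
        + [f"{m}_sq_lag" for m in motion_names]
        + ["csf", "wm"]
    )
    return NuisanceMatrix(values=cols, names=tuple(names))


@dataclass(frozen=True)
class NuisanceMatrix:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        if self.values.shape[1] != len(self.names):
            raise ValueError("nuisance column count does not match names")


@dataclass(frozen=True)
class FeatureMatrix:
    """TR x in-mask-voxel matrix with its normalization state and voxel map.

    ``voxel_indices`` maps feature columns back to flat voxel indices of the
    source grid; ``valid`` marks columns kept (e.g., nonzero-mean voxels in
    percent-signal-change mode).
    """

    values: np.ndarray
    state: str  # raw | psc | zscored | detrended | highpass
    voxel_indices: np.ndarray | None = None
    grid_shape: tuple[int, ...] | None = None


def _dct_drift_basis(n: int, tr_seconds: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors with period longer than ``cutoff_s``."""
    order = int(np.floor(2 * n * tr_seconds / cutoff_s))
    t = np.arange(n)
    cols = [np.ones(n)]
    for k in range(1, order + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / n))
    return np.column_stack(cols)


def normalize(
    features: np.ndarray | FeatureMatrix,
    mode: str,
    censor: CensorMask | None = None,
    tr_seconds: float = 2.0,
    cutoff_s: float = 128.0,
) -> FeatureMatrix:
    """Normalize per-voxel time courses.

    Modes: ``psc`` rescales to percent signal change, 100*(x-mean)/mean;
    ``zscore`` standardizes each voxel over uncensored TRs; ``detrend``
    removes a linear trend; ``highpass128`` removes slow drift by regressing
    out a discrete-cosine basis with period above ``cutoff_s`` seconds.
    Censored TRs are excluded from the statistics/fits but every row is
    transformed, so output length always matches input length.
    """
    if isinstance(features, FeatureMatrix):
        x = features.values
        vidx, grid = features.voxel_indices, features.grid_shape
    elif hasattr(features, "to_features"):  # a VolumeSeries
        x = features.to_features()
        vidx, grid = features.voxel_indices, features.mask.shape
    else:
        x = np.asarray(features, dtype=float)
        vidx, grid = None, None
    if x.ndim != 2:
        raise ValueError("features must be a TR x voxel matrix")
    keep = censor.keep if censor is not None else np.ones(x.shape[0], dtype=bool)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 uncensored TRs")
    xk = x[keep]

    if mode == "psc":
        mean = xk.mean(axis=0)
        valid = np.abs(mean) > 1e-12
        out = np.zeros_like(x)
        out[:, valid] = 100.0 * (x[:, valid] - mean[valid]) / mean[valid]
        if not valid.all():
            out = out[:, valid]
            vidx = vidx[valid] if vidx is not None else None
        return FeatureMatrix(values=out, state="psc", voxel_indices=vidx, grid_shape=grid)
    if mode == "zscore":
        mean = xk.mean(axis=0)
        sd = xk.std(axis=0, ddof=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
        out = (x - mean) / sd
        return FeatureMatrix(values=out, state="zscored", voxel_indices=vidx, grid_shape=grid)
    if mode == "detrend":
        t = np.arange(x.shape[0], dtype=float)
        basis = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(basis[keep], xk, rcond=None)
        out = x - basis @ beta
        return FeatureMatrix(values=out, state="detrended", voxel_indices=vidx, grid_shape=grid)
    if mode == "highpass128":
        basis = _dct_drift_basis(x.shape[0], tr_seconds, cutoff_s)
        beta, *_ = np.linalg.lstsq(basis[keep], xk, rcond=None)
        out = x - basis @ beta
        return FeatureMatrix(values=out, state="highpass", voxel_indices=vidx, grid_shape=grid)
    raise ValueError(f"unknown normalization mode {mode!r}")


def gaussian_smooth(
    data: np.ndarray, fwhm_mm: float, voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
) -> np.ndarray:
    """Spatially smooth a 3D volume or 4D (x, y, z, t) series.

    Sigma per axis is fwhm / (2*sqrt(2*ln 2)) in voxel units; ``fwhm_mm=0``
    is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if hasattr(data, "data") and hasattr(data, "mask"):  # a VolumeSeries
        data = data.data
    if fwhm_mm == 0:
        return np.asarray(data, dtype=float).copy()
    data = np.asarray(data, dtype=float)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size_mm)
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox)
    if data.ndim == 4:
        return ndimage.gaussian_filter(data, sigma=(*sigma_vox, 0.0))
    raise ValueError("expected a 3D volume or 4D series")
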