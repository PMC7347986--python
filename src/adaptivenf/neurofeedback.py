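"""The adaptive real-time loop: per-TR normalization, hyperplane prediction,
and the opacity transform chain.

A feedback run begins with 20 resting TRs (40 s) that accumulate voxel time
courses for incremental detrending and z-scoring; no prediction is emitted
during this warmup. From TR 21 on, each incoming volume is normalized
against everything accumulated so far, the SVM produces a hyperplane
distance (HD), and the HD passes through a sigmoid, is scaled into the
0.17–0.83 opacity range (both stimuli always remain at least faintly
visible), is temporally smoothed (mean of the current and previous two raw
scaled values, active only after the first three values of a block), and is
finally quantized to the 0–255 alpha range of the stimulus software. Face
and word opacities move in opposing directions (they sum to 1 before
quantization). Each block starts with balanced 50/50 opacity on its first
two trials, and the opacity computed at TR t is displayed on the two trials
of TR t+1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decode import ClassifierModel, HDTrace, predict_hd
from .taskdesign import ATTEND_FACE, INSTRUCTION_NAMES, REST, RunDesign

OPACITY_MIN = 0.17
OPACITY_MAX = 0.83
OPACITY_SPAN = OPACITY_MAX - OPACITY_MIN  # 0.66
BALANCED_OPACITY = 0.5
WARMUP_TRS = 20
SMOOTH_WINDOW = 3
ALPHA_MAX = 255


class NotReadyError(RuntimeError):
    """Raised when a prediction is requested before the warmup completes."""


@dataclass
class RealtimeState:
    """Running state of the incremental normalizer and opacity smoother.

    Keeps O(voxel) running sums for the linear-trend fit (n, sum t, sum t^2,
    sum y, sum t*y, sum y^2 per voxel) so each TR costs the same regardless
    of how much data has accumulated, plus the per-block history of raw
    scaled opacities for temporal smoothing.
    """

    n_voxels: int
    warmup_trs: int = WARMUP_TRS
    n: int = 0
    _sum_t: float = 0.0
    _sum_tt: float = 0.0
    _sy: np.ndarray = None
    _sty: np.ndarray = None
    _syy: np.ndarray = None
    smoothing_history: list = field(default_factory=list)

    def __post_init__(self):
        self._sy = np.zeros(self.n_voxels)
        self._sty = np.zeros(self.n_voxels)
        self._syy = np.zeros(self.n_voxels)

    @property
    def ready(self) -> bool:
        """True once the warmup sample is complete: the next TR gets a prediction."""
        return self.n >= self.warmup_trs

    def reset_smoothing(self) -> None:
        self.smoothing_history = []


def incremental_normalize(state: RealtimeState, new_volume: np.ndarray) -> np.ndarray:
    """Ingest one raw volume; return its detrended, z-scored feature vector.

    A linear trend is fit per voxel to all TRs accumulated so far (including
    this one) and removed; the current TR's residual is then standardized by
    the running mean/sd of the residuals. Raises :class:`NotReadyError`
    while fewer than ``warmup_trs`` TRs have accumulated (the volume is
    still ingested, so warmup data contribute to the statistics).
    """
    y = np.asarray(new_volume, dtype=float)
    if len(y) != state.n_voxels:
        raise ValueError(f"volume length {len(y)} != expected {state.n_voxels}")
    t = float(state.n)
    state.n += 1
    state._sum_t += t
    state._sum_tt += t * t
    state._sy += y
    state._sty += t * y
    state._syy += y * y
    n = state.n
    if n <= state.warmup_trs:
        # this volume is part of the warmup sample itself; no prediction yet
        raise NotReadyError(f"warmup incomplete: {n}/{state.warmup_trs} TRs")

    tbar = state._sum_t / n
    stt = state._sum_tt - n * tbar * tbar
    ybar = state._sy / n
    if stt > 1e-12:
        slope = (state._sty - tbar * state._sy) / stt
    else:
        slope = np.zeros_like(ybar)
    intercept = ybar - slope * tbar
    # residual sum of squares via orthogonality of OLS residuals to the fit
    rss = state._syy - intercept * state._sy - slope * state._sty
    rss = np.maximum(rss, 0.0)
    sd = np.sqrt(rss / n)
    sd = np.where(sd > 1e-12, sd, 1.0)
    resid_t = y - (intercept + slope * t)
    return resid_t / sd


def hd_to_opacity(hd: float, slope: float = 1.0) -> float:
    """Sigmoid-transform an HD and scale it into the 17–83% opacity range.

    opacity = 0.17 + 0.66 / (1 + exp(-slope * hd)); monotone in hd, 0.5 at
    hd = 0, saturating at 0.17 and 0.83. A positive HD (attend-face-like
    state) raises face opacity.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    s = 1.0 / (1.0 + math.exp(-slope * float(np.clip(hd, -700 / slope, 700 / slope))))
    return OPACITY_MIN + OPACITY_SPAN * s


def smooth_opacity(state: RealtimeState, value: float) -> float:
    """Temporal smoothing of scaled opacities within a block.

    The first three scaled values of a block pass through unsmoothed; from
    the fourth on, the output is the mean of the current and previous two
    raw (unsmoothed) scaled values.
    """
    if not OPACITY_MIN - 1e-12 <= value <= OPACITY_MAX + 1e-12:
        raise ValueError(f"opacity {value} outside [{OPACITY_MIN}, {OPACITY_MAX}]")
    state.smoothing_history.append(float(value))
    if len(state.smoothing_history) <= SMOOTH_WINDOW:
        return float(value)
    return float(np.mean(state.smoothing_history[-SMOOTH_WINDOW:]))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def opacity_to_alpha(opacity: float) -> tuple[int, int]:
    """Map a face opacity in [0, 1] to the (alpha_face, alpha_word) pair.

    Alphas are 0–255 integers moving in opposing directions
    (round-half-away-from-zero): 0.5 -> (128, 128), 1.0 -> (255, 0).
    """
    if not 0.0 <= opacity <= 1.0:
        raise ValueError(f"opacity {opacity} outside [0, 1]")
    return _round_half_away(ALPHA_MAX * opacity), _round_half_away(ALPHA_MAX * (1.0 - opacity))


@dataclass(frozen=True)
class SessionTrace:
    """Per-TR record of one closed-loop run.

    Columns: tr_index, block, instruction, hd, sigmoid, opacity_raw,
    opacity_smoothed, alpha_face, alpha_word, target_opacity, valid.
    Opacity columns refer to the face stimulus; the word opacity is their
    complement. ``target_opacity`` is what was actually on screen during
    that TR's two trials (NaN during rest).
    """

    frame: pd.DataFrame
    design: RunDesign
    subject_id: str = ""
    seed: int = 0

    def hd_trace(self) -> HDTrace:
        return HDTrace(
            values=self.frame["hd"].to_numpy(),
            valid=self.frame["valid"].to_numpy(dtype=bool),
        )

    def to_tsv(self, path) -> None:
        cols = [
            "tr_index", "block", "instruction", "hd", "sigmoid",
            "opacity_raw", "opacity_smoothed", "alpha_face", "alpha_word",
            "target_opacity", "valid",
        ]
        self.frame[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_session_trace(path, design: RunDesign | None = None) -> SessionTrace:
    frame = pd.read_csv(path, sep="\t")
    frame["valid"] = frame["valid"].astype(bool)
    return SessionTrace(frame=frame, design=design)


def run_closed_loop(
    spec,
    model: ClassifierModel,
    design: RunDesign,
    seed: int = 0,
    slope: float = 1.0,
    warmup_trs: int = WARMUP_TRS,
) -> SessionTrace:
    """Simulate one adaptive neurofeedback run end to end.

    Per TR the synthetic brain (responsive to the opacity currently on
    screen) emits a volume, which is incrementally normalized and scored by
    the classifier; the HD passes through the opacity chain, and the result
    is displayed on the next TR's trials. In attend-to-word blocks the HD is
    negated before the sigmoid so that moving away from the instructed state
    always masks the target. Each block starts balanced (0.5/0.5, smoothing
    history reset). Deterministic given (spec, model, design, seed).
    """
    from .synthdata import RunSimulator

    if model.n_features != spec.n_mask_voxels:
        raise ValueError(
            f"model has {model.n_features} features but subject mask has "
            f"{spec.n_mask_voxels} voxels"
        )
    if design.initial_rest_trs < warmup_trs:
        raise ValueError(
            f"design provides {design.initial_rest_trs} initial rest TRs; "
            f"warmup needs {warmup_trs}"
        )

    sim = RunSimulator(spec, design, run_index=seed)
    state = RealtimeState(n_voxels=spec.n_mask_voxels, warmup_trs=warmup_trs)
    block_idx = design.block_index_per_tr()

    pending_face_opacity: float | None = None  # computed at t, shown at t+1
    rows = []
    target_per_tr = np.full(design.n_trs, np.nan)

    for t in range(design.n_trs):
        label = design.tr_labels[t]
        block_start = label != REST and (t == 0 or block_idx[t] != block_idx[t - 1])
        if block_start:
            state.reset_smoothing()
            face_shown = BALANCED_OPACITY
        elif label != REST and pending_face_opacity is not None:
            face_shown = pending_face_opacity
        else:
            face_shown = None

        if face_shown is not None:
            target = face_shown if label == ATTEND_FACE else 1.0 - face_shown
            target_per_tr[t] = target
        else:
            target = None

        volume = sim.step(target)
        try:
            feats = incremental_normalize(state, volume)
        except NotReadyError:
            rows.append(
                {"tr_index": t, "block": block_idx[t], "instruction": INSTRUCTION_NAMES[label],
                 "hd": np.nan, "sigmoid": np.nan, "opacity_raw": np.nan,
                 "opacity_smoothed": np.nan, "alpha_face": -1, "alpha_word": -1,
                 "target_opacity": np.nan, "valid": False}
            )
            pending_face_opacity = None
            continue

        hd = predict_hd(model, feats)
        face_raw = hd_to_opacity(hd, slope=slope)
        sig = (face_raw - OPACITY_MIN) / OPACITY_SPAN
        if label != REST:
            face_smoothed = smooth_opacity(state, face_raw)
            pending_face_opacity = face_smoothed
        else:
            face_smoothed = np.nan
            pending_face_opacity = None
        alpha = opacity_to_alpha(face_smoothed) if label != REST else (-1, -1)
        rows.append(
            {"tr_index": t, "block": block_idx[t], "instruction": INSTRUCTION_NAMES[label],
             "hd": hd, "sigmoid": sig, "opacity_raw": face_raw,
             "opacity_smoothed": face_smoothed, "alpha_face": alpha[0],
             "alpha_word": alpha[1], "target_opacity": target_per_tr[t],
             "valid": True}
        )

    frame = pd.DataFrame(rows)
    return SessionTrace(frame=frame, design=design, subject_id=spec.subject_id, seed=seed)
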