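"""Synthetic subjects, runs, motion, and behavior for the neurofeedback pipeline.

No imaging data are distributed with this package; this module generates 4D
BOLD series with the statistical structure the analysis chain assumes. Each
synthetic subject carries two spatially distinct multivoxel activation
patterns (an attend-face pattern and an attend-word pattern) on a small
ellipsoidally masked grid. A latent attention state s_t in [0, 1] follows a
bounded mean-reverting update: it is pulled toward the instructed state with
a weight given by the subject's compliance, degraded during trauma-word
blocks by a valence attenuation factor (below 1 only in the PTSD group), and
— in closed-loop mode — pulled further toward the target in proportion to
the current feedback opacity. The noiseless BOLD signal is the HRF-convolved
mixture s_t * pattern_face + (1 - s_t) * pattern_word during stimulation,
on top of a constant baseline, slow sinusoidal drift and AR(1) Gaussian
noise. Head motion is smooth low-amplitude drift plus occasional spikes
large enough to trip the 0.4 mm framewise-displacement censor.

Behavior is not modeled mechanistically: the probability of a correct no-go
withhold is logistic in the target-stimulus opacity and the subject's
compliance, which is all the downstream sensitivity analyses require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .analysis import canonical_hrf
from .taskdesign import (
    ATTEND_FACE,
    REST,
    TRAUMA,
    ResponseLog,
    RunDesign,
    sample_trials,
)

GROUP_PTSD = 1
GROUP_CONTROL = -1
GROUP_NAMES = {GROUP_PTSD: "ptsd", GROUP_CONTROL: "control"}

BASELINE = 100.0  # arbitrary scanner units; nonzero so percent signal change is defined

# behavioral response model: P(correct no-go) = logistic(b0 + b1*opacity + b2*compliance)
NOGO_B0 = -3.3
GO_B0 = 0.0
BEHAV_B_OPACITY = 1.5
BEHAV_B_COMPLIANCE = 5.0

_STATE_PULL = 1.0  # rate of mean reversion toward the engagement level


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """All parameters of one synthetic subject.

    ``pattern_face`` and ``pattern_word`` are 3D amplitude maps (a.u.),
    nonzero only inside ``mask``; their expected difference scales with
    ``separability``. ``valence_attenuation`` multiplies the attention pull
    during trauma-word blocks (PTSD group only at defaults), ``compliance``
    weights how strongly the latent state follows the instruction, and
    ``responsiveness`` is the gain with which feedback opacity pulls the
    state toward the target in closed-loop runs.
    """

    subject_id: str
    group: int  # GROUP_PTSD or GROUP_CONTROL
    seed: int
    grid_shape: tuple[int, int, int]
    mask: np.ndarray
    pattern_face: np.ndarray
    pattern_word: np.ndarray
    separability: float
    valence_attenuation: float
    compliance: float
    responsiveness: float
    noise_sd: float
    ar1_coef: float
    drift_amplitude: float
    motion_spike_rate: float
    state_noise_sd: float = 0.05
    compliance_run_decrement: float = 0.0
    age: float = 35.0
    education: float = 14.0

    def __post_init__(self):
        if self.group not in (GROUP_PTSD, GROUP_CONTROL):
            raise ValueError("group must be +1 (PTSD) or -1 (control)")
        checks = {
            "separability": (0.0, np.inf),
            "valence_attenuation": (0.0, 1.0),
            "compliance": (0.0, 1.0),
            "responsiveness": (0.0, np.inf),
            "ar1_coef": (0.0, 1.0 - 1e-12),
            "drift_amplitude": (0.0, np.inf),
            "motion_spike_rate": (0.0, 1.0),
            "state_noise_sd": (0.0, np.inf),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("pattern_face", "pattern_word"):
            p = getattr(self, name)
            if p.shape != tuple(self.grid_shape):
                raise ValueError(f"{name} shape does not match grid_shape")
            if np.any(p[~self.mask] != 0):
                raise ValueError(f"{name} is nonzero outside the mask")

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class VolumeSeries:
    """4D (x, y, z, t) BOLD array with its gray-matter mask and TR."""

    data: np.ndarray
    mask: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match volume grid")

    @property
    def n_trs(self) -> int:
        return self.data.shape[3]

    def to_features(self) -> np.ndarray:
        """TR x in-mask-voxel matrix (mask applied in C order)."""
        return self.data[self.mask].T.copy()

    @property
    def voxel_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())


def ellipsoid_mask(grid_shape: tuple[int, int, int], radius_frac: float = 0.92) -> np.ndarray:
    """Centered ellipsoidal mask; at the 12x12x12 default ~700 voxels."""
    shape = np.asarray(grid_shape)
    center = (shape - 1) / 2.0
    radii = radius_frac * shape / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def _smooth_field(rng: np.random.Generator, mask: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Spatially smooth unit-RMS random field restricted to the mask."""
    field = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=sigma)
    field[~mask] = 0.0
    rms = np.sqrt(np.mean(field[mask] ** 2))
    field[mask] /= rms
    return field


_GROUP_DEFAULTS = {
    GROUP_CONTROL: {"valence_attenuation": 1.0, "compliance": 0.78},
    GROUP_PTSD: {"valence_attenuation": 0.6, "compliance": 0.62},
}

_COMMON_DEFAULTS = {
    "grid_shape": (12, 12, 12),
    "separability": 0.25,
    "responsiveness": 0.3,
    "noise_sd": 1.0,
    "ar1_coef": 0.3,
    "drift_amplitude": 0.5,
    "motion_spike_rate": 0.02,
    "state_noise_sd": 0.05,
    "compliance_run_decrement": 0.0,
    "age": 35.0,
    "education": 14.0,
}


def _coerce_group(group) -> int:
    if isinstance(group, str):
        lookup = {v: k for k, v in GROUP_NAMES.items()}
        if group.lower() not in lookup:
            raise ValueError(f"unknown group {group!r}")
        return lookup[group.lower()]
    if group in (GROUP_PTSD, GROUP_CONTROL):
        return int(group)
    raise ValueError(f"unknown group {group!r}")


def make_subject_spec(group, seed: int, overrides: dict | None = None) -> SyntheticSubjectSpec:
    """Build a subject spec with group-dependent defaults.

    Control subjects default to ``valence_attenuation=1.0`` (no trauma-block
    degradation); PTSD subjects default to 0.6, so trauma blocks reduce
    pattern separability only in the PTSD group. Deterministic given
    (group, seed, overrides); unknown override keys are rejected by name.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    group = _coerce_group(group)
    overrides = dict(overrides or {})
    params = dict(_COMMON_DEFAULTS) | dict(_GROUP_DEFAULTS[group])
    settable = set(params) | {"subject_id"}
    unknown = set(overrides) - settable
    if unknown:
        raise ValueError(f"unknown override keys: {sorted(unknown)}")
    params |= overrides
    subject_id = params.pop("subject_id", f"{GROUP_NAMES[group]}-{seed:04d}")

    grid_shape = tuple(params.pop("grid_shape"))
    mask = ellipsoid_mask(grid_shape)
    rng = np.random.default_rng([int(seed), 2911])
    base = 0.5 * _smooth_field(rng, mask)
    diff = _smooth_field(rng, mask)
    sep = float(params["separability"])
    pattern_face = base + 0.5 * sep * diff
    pattern_word = base - 0.5 * sep * diff

    return SyntheticSubjectSpec(
        subject_id=subject_id,
        group=group,
        seed=int(seed),
        grid_shape=grid_shape,
        mask=mask,
        pattern_face=pattern_face,
        pattern_word=pattern_word,
        **params,
    )


def _motion_trace(rng: np.random.Generator, n_trs: int, tr_seconds: float,
                  spike_rate: float) -> np.ndarray:
    """Smooth low-amplitude drift plus transient spikes on one translation axis."""
    t = np.arange(n_trs) * tr_seconds
    vals = np.zeros((n_trs, 6))
    for j in range(6):
        amp = rng.uniform(0.01, 0.05)
        period = rng.uniform(60.0, 240.0)
        phase = rng.uniform(0, 2 * np.pi)
        vals[:, j] = amp * np.sin(2 * np.pi * t / period + phase)
    spikes = rng.random(n_trs) < spike_rate
    spikes[0] = False
    for i in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        vals[i, axis] += rng.uniform(0.5, 1.5)  # guarantees FD > 0.4 mm
    return vals


class RunSimulator:
    """Stepwise per-TR generator for one run of one synthetic subject.

    The closed-loop driver calls :meth:`step` once per TR, passing the
    target-stimulus opacity currently on screen (or ``None`` during rest /
    open-loop runs, treated as the balanced 0.5); the simulator returns the
    raw in-mask voxel vector for that TR. Noise, drift, motion and the state
    innovations are pre-drawn from the subject seed, so a run is bit-identical
    whenever the sequence of opacities fed in is identical.
    """

    def __init__(self, spec: SyntheticSubjectSpec, design: RunDesign, run_index: int = 0):
        self.spec = spec
        self.design = design
        self.run_index = run_index
        n, v = design.n_trs, spec.n_mask_voxels
        rng = np.random.default_rng([spec.seed, run_index, 7177])

        # AR(1) noise with stationary sd = noise_sd, pre-drawn for the whole run
        phi, sd = spec.ar1_coef, spec.noise_sd
        innov = rng.standard_normal((n, v)) * sd * np.sqrt(1.0 - phi**2)
        noise = np.empty((n, v))
        noise[0] = rng.standard_normal(v) * sd
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + innov[i]
        self._noise = noise

        tsec = np.arange(n) * design.tr_seconds
        period = rng.uniform(100.0, 300.0, size=v)
        phase = rng.uniform(0, 2 * np.pi, size=v)
        self._drift = spec.drift_amplitude * np.sin(
            2 * np.pi * tsec[:, None] / period[None, :] + phase[None, :]
        )

        self.motion = _motion_trace(rng, n, design.tr_seconds, spec.motion_spike_rate)
        self._state_innov = rng.standard_normal(n) * spec.state_noise_sd
        self.behavior_rng = np.random.default_rng([spec.seed, run_index, 3301])

        self._pf = spec.pattern_face[spec.mask]
        self._pw = spec.pattern_word[spec.mask]
        self._hrf = canonical_hrf(design.tr_seconds)
        self._block_idx = design.block_index_per_tr()
        self._activation = np.zeros((n, v))
        self._compliance = max(
            0.0, spec.compliance - run_index * spec.compliance_run_decrement
        )
        self.t = 0
        self.s = 0.5
        self.state_trace = np.full(n, np.nan)

    def step(self, target_opacity: float | None = None) -> np.ndarray:
        """Advance one TR; returns the raw in-mask voxel vector."""
        t = self.t
        if t >= self.design.n_trs:
            raise IndexError("run already complete")
        spec = self.spec
        label = self.design.tr_labels[t]
        valence = self.design.tr_valence[t]

        if label == REST:
            s_instructed = 0.5
            level = 0.5
        else:
            s_instructed = 1.0 if label == ATTEND_FACE else 0.0
            atten = (
                spec.valence_attenuation
                if (spec.group == GROUP_PTSD and valence == TRAUMA)
                else 1.0
            )
            # compliance (attenuated on PTSD trauma blocks) sets the sustained
            # engagement level, not just the approach rate: a half-compliant
            # subject's state settles halfway between neutral and instructed
            level = 0.5 + self._compliance * atten * (s_instructed - 0.5)

        delta = _STATE_PULL * (level - self.s)
        if target_opacity is not None and label != REST:
            delta += spec.responsiveness * (target_opacity - 0.5) * (s_instructed - self.s)
        self.s = float(np.clip(self.s + delta + self._state_innov[t], 0.0, 1.0))
        self.state_trace[t] = self.s

        if label != REST:
            self._activation[t] = self.s * self._pf + (1.0 - self.s) * self._pw

        k = min(t + 1, len(self._hrf))
        signal = self._hrf[:k] @ self._activation[t - k + 1 : t + 1][::-1]
        self.t += 1
        return BASELINE + signal + self._drift[t] + self._noise[t]

    def behavior(self, opacity_per_tr: np.ndarray) -> ResponseLog:
        """Draw the per-trial response log given the realized opacity trace."""
        spec, design = self.spec, self.design
        rng = self.behavior_rng
        rows = []
        trial_counter = 0
        for k, block in enumerate(design.blocks):
            trials = sample_trials(block, seed=int(rng.integers(2**31)))
            for j, trial in enumerate(trials):
                tr_idx = int(trial.onset_s / design.tr_seconds)
                opacity = float(opacity_per_tr[tr_idx])
                logit_common = BEHAV_B_OPACITY * opacity + BEHAV_B_COMPLIANCE * self._compliance
                if trial.is_nogo:
                    p_correct = _logistic(NOGO_B0 + logit_common)
                    correct = rng.random() < p_correct
                    responded_yes = not correct
                else:
                    p_yes = _logistic(GO_B0 + logit_common)
                    responded_yes = rng.random() < p_yes
                    correct = responded_yes
                rows.append(
                    {
                        "trial_index": trial_counter,
                        "block_index": k,
                        "is_nogo": trial.is_nogo,
                        "responded_yes": responded_yes,
                        "correct": correct,
                        "instruction": block.instruction,
                        "valence": block.valence,
                        "opacity": opacity,
                        "run": self.run_index,
                    }
                )
                trial_counter += 1
        return ResponseLog(trials=pd.DataFrame(rows))


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_run(
    spec: SyntheticSubjectSpec,
    design: RunDesign,
    opacity_trace: np.ndarray | None = None,
    run_index: int = 0,
):
    """Simulate one full run open-loop.

    ``opacity_trace`` (per-TR target-stimulus opacity) drives the feedback
    term and the behavioral model when present; otherwise the balanced 0.5
    is used throughout, matching the static-opacity training runs. Returns
    ``(VolumeSeries, MotionTrace, ResponseLog)``, bit-identical for
    identical inputs.
    """
    from .preproc import MotionTrace

    if opacity_trace is not None and len(opacity_trace) != design.n_trs:
        raise ValueError(
            f"opacity_trace length {len(opacity_trace)} != design TRs {design.n_trs}"
        )
    sim = RunSimulator(spec, design, run_index=run_index)
    n, v = design.n_trs, spec.n_mask_voxels
    feats = np.empty((n, v))
    for t in range(n):
        op = None if opacity_trace is None else float(opacity_trace[t])
        feats[t] = sim.step(op)

    data = np.zeros((*spec.grid_shape, n))
    data[spec.mask] = feats.T
    volumes = VolumeSeries(data=data, mask=spec.mask, tr_seconds=design.tr_seconds)
    motion = MotionTrace(values=sim.motion, tr_seconds=design.tr_seconds)
    opacity_per_tr = (
        np.full(n, 0.5) if opacity_trace is None else np.asarray(opacity_trace, dtype=float)
    )
    log = sim.behavior(opacity_per_tr)
    return volumes, motion, log


# cohort-level heterogeneity (SD or ranges of the per-subject draws)
_COHORT_JITTER = {
    "compliance_sd": 0.12,
    "separability_sd": 0.02,
    "noise_sd_sd": 0.05,
    "ptsd_attenuation_range": (0.25, 0.95),
    "age_range": (22, 55),
    "education_range": (10, 20),
}


def generate_cohort(
    n_ptsd: int = 10, n_control: int = 9, seed: int = 0
) -> list[SyntheticSubjectSpec]:
    """Draw a cohort of subject specs (defaults: 10 PTSD, 9 controls).

    Per-subject parameters are jittered around the group defaults so that
    between-subject regressions (e.g. classifier accuracy predicting
    sensitivity) have real variance to work with; per-subject seeds derive
    deterministically from the master seed.
    """
    if n_ptsd < 0 or n_control < 0:
        raise ValueError("cohort sizes must be non-negative")
    master = np.random.default_rng([int(seed), 9003])
    specs = []
    groups = [GROUP_PTSD] * n_ptsd + [GROUP_CONTROL] * n_control
    for i, group in enumerate(groups):
        sub_seed = int(master.integers(2**31))
        rng = np.random.default_rng([sub_seed, 17])
        base = dict(_GROUP_DEFAULTS[group])
        overrides = {
            "compliance": float(
                np.clip(
                    rng.normal(base["compliance"], _COHORT_JITTER["compliance_sd"]), 0.35, 0.98
                )
            ),
            "separability": float(
                max(0.05, rng.normal(_COMMON_DEFAULTS["separability"], _COHORT_JITTER["separability_sd"]))
            ),
            "noise_sd": float(
                max(0.5, rng.normal(_COMMON_DEFAULTS["noise_sd"], _COHORT_JITTER["noise_sd_sd"]))
            ),
            "age": float(rng.uniform(*_COHORT_JITTER["age_range"])),
            "education": float(rng.uniform(*_COHORT_JITTER["education_range"])),
            "subject_id": f"{GROUP_NAMES[group]}-{i:03d}",
        }
        if group == GROUP_PTSD:
            overrides["valence_attenuation"] = float(
                rng.uniform(*_COHORT_JITTER["ptsd_attenuation_range"])
            )
        specs.append(make_subject_spec(group, seed=sub_seed, overrides=overrides))
    return specs
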