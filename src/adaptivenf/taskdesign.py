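"""Training and neurofeedback run designs, trial sampling, and behavioral scoring.

The task is an implicit emotion-regulation go/no-go paradigm: composite
word-on-face stimuli are shown in 30-trial blocks (1 s per trial), and the
participant attends either to the word or to the face. Training runs use a
2 (attention) x 2 (word valence) factorial design with three blocks per cell;
neurofeedback runs use six attend-to-face and six attend-to-word blocks, all
with trauma-dominant words. Blocks are separated by 8 s of rest.

Behavioral sensitivity is scored as no-go accuracy (withholding the prepotent
"yes" response on the rare non-dominant trials), with d-prime available as an
alternative measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ATTEND_FACE = 1
ATTEND_WORD = -1
REST = 0
TRAUMA = 1
NEUTRAL = -1

INSTRUCTION_NAMES = {ATTEND_FACE: "attend_face", ATTEND_WORD: "attend_word", REST: "rest"}
VALENCE_NAMES = {TRAUMA: "trauma", NEUTRAL: "neutral", REST: "rest"}


@dataclass(frozen=True)
class Block:
    """One task block: an instruction, a dominant word valence, and trial counts."""

    instruction: int  # ATTEND_FACE or ATTEND_WORD
    valence: int  # TRAUMA or NEUTRAL (dominant word category)
    onset_s: float
    n_trials: int = 30
    trial_duration_s: float = 1.0
    dominant_word_fraction: float = 0.9
    female_face_fraction: float = 0.9
    go_fraction: float = 0.9

    def __post_init__(self):
        if self.instruction not in (ATTEND_FACE, ATTEND_WORD):
            raise ValueError(f"instruction must be ±1, got {self.instruction}")
        if self.valence not in (TRAUMA, NEUTRAL):
            raise ValueError(f"valence must be ±1, got {self.valence}")
        for name in ("dominant_word_fraction", "female_face_fraction", "go_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.trial_duration_s


@dataclass(frozen=True)
class TrialEvent:
    """A single 1 s composite stimulus: a word category, a face category, go/no-go."""

    onset_s: float
    word_category: str  # "trauma" or "neutral"
    face_category: str  # "female" or "male"
    is_nogo: bool


@dataclass(frozen=True)
class RunDesign:
    """Ordered blocks plus the TR grid they tile — the experiment's clock.

    ``tr_labels`` holds one instruction code per TR (0 rest, +1 attend-face,
    -1 attend-word) and ``tr_valence`` the dominant word valence of the
    enclosing block (0 during rest).
    """

    blocks: tuple[Block, ...]
    tr_seconds: float
    rest_duration_s: float = 8.0
    initial_rest_trs: int = 0
    tr_labels: np.ndarray = field(default=None, compare=False)
    tr_valence: np.ndarray = field(default=None, compare=False)

    def __post_init__(self):
        labels, valence = self._tile()
        object.__setattr__(self, "tr_labels", labels)
        object.__setattr__(self, "tr_valence", valence)

    def _tile(self) -> tuple[np.ndarray, np.ndarray]:
        tr = self.tr_seconds
        total_s = self.initial_rest_trs * tr + sum(
            b.duration_s + self.rest_duration_s for b in self.blocks
        )
        n_trs = total_s / tr
        if abs(n_trs - round(n_trs)) > 1e-9:
            raise ValueError(
                f"block/rest durations do not tile the TR grid: {total_s} s at TR {tr} s"
            )
        n_trs = int(round(n_trs))
        labels = np.zeros(n_trs, dtype=int)
        valence = np.zeros(n_trs, dtype=int)
        for b in self.blocks:
            i0 = b.onset_s / tr
            if abs(i0 - round(i0)) > 1e-9:
                raise ValueError(f"block onset {b.onset_s} s not on the TR grid")
            i0 = int(round(i0))
            n = int(round(b.duration_s / tr))
            labels[i0 : i0 + n] = b.instruction
            valence[i0 : i0 + n] = b.valence
        return labels, valence

    @property
    def n_trs(self) -> int:
        return len(self.tr_labels)

    @property
    def duration_s(self) -> float:
        return self.n_trs * self.tr_seconds

    def block_index_per_tr(self) -> np.ndarray:
        """-1 during rest, otherwise the index of the enclosing block."""
        idx = np.full(self.n_trs, -1, dtype=int)
        for k, b in enumerate(self.blocks):
            i0 = int(round(b.onset_s / self.tr_seconds))
            n = int(round(b.duration_s / self.tr_seconds))
            idx[i0 : i0 + n] = k
        return idx

    def to_events(self) -> pd.DataFrame:
        rows = [
            {
                "onset": b.onset_s,
                "duration": b.duration_s,
                "trial_type": INSTRUCTION_NAMES[b.instruction],
                "valence": VALENCE_NAMES[b.valence],
            }
            for b in self.blocks
        ]
        return pd.DataFrame(rows)


def _block_sequence(onsets_from: float, combos: list[tuple[int, int]],
                    rest_duration_s: float, **block_kwargs) -> tuple[Block, ...]:
    blocks = []
    onset = onsets_from
    for instr, val in combos:
        b = Block(instruction=instr, valence=val, onset_s=onset, **block_kwargs)
        blocks.append(b)
        onset += b.duration_s + rest_duration_s
    return tuple(blocks)


def build_training_design(tr_seconds: float = 2.0, seed: int = 0) -> RunDesign:
    """Twelve-block factorial training run.

    Six attend-to-face blocks (three with 90% neutral words, three with 90%
    trauma words) and six attend-to-word blocks likewise, in an order
    pseudo-randomized from ``seed``. Every block has 30 one-second trials,
    90% female faces and 90% go trials, with 8 s rest after each block.
    """
    rng = np.random.default_rng(seed)
    combos = [
        (instr, val)
        for instr in (ATTEND_FACE, ATTEND_WORD)
        for val in (TRAUMA, NEUTRAL)
        for _ in range(3)
    ]
    order = rng.permutation(len(combos))
    combos = [combos[i] for i in order]
    blocks = _block_sequence(0.0, combos, 8.0)
    return RunDesign(blocks=blocks, tr_seconds=tr_seconds, initial_rest_trs=0)


def build_feedback_design(tr_seconds: float = 2.0, seed: int = 0) -> RunDesign:
    """Twelve-block neurofeedback run: 6 attend-to-face + 6 attend-to-word,
    all blocks trauma-dominant, preceded by 20 resting TRs (40 s at TR 2 s)."""
    rng = np.random.default_rng(seed)
    combos = [(instr, TRAUMA) for instr in (ATTEND_FACE, ATTEND_WORD) for _ in range(6)]
    order = rng.permutation(len(combos))
    combos = [combos[i] for i in order]
    initial_rest_trs = 20
    blocks = _block_sequence(initial_rest_trs * tr_seconds, combos, 8.0)
    return RunDesign(
        blocks=blocks, tr_seconds=tr_seconds, initial_rest_trs=initial_rest_trs
    )


def _nonadjacent_positions(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k positions out of n with no two adjacent, uniformly via rejection."""
    if k == 0:
        return np.empty(0, dtype=int)
    if k > (n + 1) // 2:
        raise ValueError(f"cannot place {k} non-adjacent positions in {n}")
    while True:
        pos = np.sort(rng.choice(n, size=k, replace=False))
        if k == 1 or np.all(np.diff(pos) > 1):
            return pos


def sample_trials(block: Block, seed: int = 0) -> list[TrialEvent]:
    """Draw the trial sequence of one block with exact category counts.

    Counts are exact integer allocations (round to nearest): at defaults,
    27/30 go trials, 27/30 dominant-valence words, 27/30 female faces. No two
    no-go trials are adjacent. When the minority count of the attended
    category equals the no-go count, the rare attended stimuli sit exactly on
    the no-go trials (a "no" response is a correct rare-category
    identification); otherwise categories are drawn independently.
    """
    rng = np.random.default_rng(seed)
    n = block.n_trials
    n_go = int(round(block.go_fraction * n))
    n_nogo = n - n_go
    n_dom_word = int(round(block.dominant_word_fraction * n))
    n_female = int(round(block.female_face_fraction * n))

    nogo_pos = _nonadjacent_positions(n, n_nogo, rng)
    is_nogo = np.zeros(n, dtype=bool)
    is_nogo[nogo_pos] = True

    dom_word = VALENCE_NAMES[block.valence]
    rare_word = VALENCE_NAMES[-block.valence]

    def categorize(n_major: int, major: str, minor: str, attended: bool) -> list[str]:
        n_minor = n - n_major
        cats = np.array([major] * n, dtype=object)
        if attended and n_minor == n_nogo:
            cats[nogo_pos] = minor
        else:
            cats[rng.choice(n, size=n_minor, replace=False)] = minor
        return list(cats)

    word_attended = block.instruction == ATTEND_WORD
    words = categorize(n_dom_word, dom_word, rare_word, word_attended)
    faces = categorize(n_female, "female", "male", not word_attended)

    return [
        TrialEvent(
            onset_s=block.onset_s + i * block.trial_duration_s,
            word_category=words[i],
            face_category=faces[i],
            is_nogo=bool(is_nogo[i]),
        )
        for i in range(n)
    ]


def trials_to_events(trials: list[TrialEvent], trial_duration_s: float = 1.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset": [t.onset_s for t in trials],
            "duration": trial_duration_s,
            "trial_type": ["nogo" if t.is_nogo else "go" for t in trials],
            "valence": [t.word_category for t in trials],
            "face_category": [t.face_category for t in trials],
            "is_nogo": [int(t.is_nogo) for t in trials],
        }
    )


@dataclass
class ResponseLog:
    """Per-trial button responses for one or more runs.

    ``trials`` columns: trial_index, block_index, is_nogo, responded_yes,
    correct, plus optional grouping columns (instruction, valence, run).
    """

    trials: pd.DataFrame

    REQUIRED = ("trial_index", "block_index", "is_nogo", "responded_yes", "correct")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.trials.columns]
        if missing:
            raise ValueError(f"ResponseLog missing columns: {missing}")
        t = self.trials
        # correct must be consistent with the go/no-go contingency
        expect = np.where(t["is_nogo"], ~t["responded_yes"].astype(bool), t["responded_yes"].astype(bool))
        if not np.array_equal(expect, t["correct"].to_numpy(dtype=bool)):
            raise ValueError("correct column inconsistent with is_nogo/responded_yes")
        keys = ["run", "trial_index"] if "run" in t.columns else ["trial_index"]
        if t.duplicated(subset=keys).any():
            raise ValueError("duplicate trial indices within a run")


def _dprime(n_go: int, hits: int, n_nogo: int, fas: int) -> float:
    """d' with the log-linear correction: rates (x+0.5)/(n+1)."""
    from scipy.stats import norm

    hr = (hits + 0.5) / (n_go + 1)
    far = (fas + 0.5) / (n_nogo + 1)
    return float(norm.ppf(hr) - norm.ppf(far))


def score_sensitivity(
    log: ResponseLog, by: str = "block", measure: str = "nogo_accuracy"
) -> pd.DataFrame:
    """Score behavioral sensitivity per grouping cell.

    ``measure='nogo_accuracy'`` (default, the plotted measure) is the
    proportion of no-go trials with a correctly withheld response;
    ``measure='dprime'`` is z(hit rate) - z(false-alarm rate) with the
    log-linear correction. Cells without any no-go trial are flagged
    ``undefined`` (value NaN), never silently 0.
    """
    t = log.trials
    if len(t) == 0:
        raise ValueError("empty response log")
    if by == "block":
        keys = [k for k in ("run", "block_index") if k in t.columns]
    elif by == "run":
        keys = ["run"] if "run" in t.columns else []
    elif by == "condition":
        keys = [k for k in ("instruction", "valence") if k in t.columns]
        if not keys:
            raise ValueError("log has no instruction/valence columns for by='condition'")
    else:
        raise ValueError(f"unknown grouping {by!r}")

    groups = t.groupby(keys, sort=True) if keys else [((), t)]
    rows = []
    for key, g in groups:
        key = key if isinstance(key, tuple) else (key,)
        nogo = g[g["is_nogo"].astype(bool)]
        go = g[~g["is_nogo"].astype(bool)]
        undefined = len(nogo) == 0
        if measure == "nogo_accuracy":
            value = np.nan if undefined else float(nogo["correct"].mean())
        elif measure == "dprime":
            value = (
                np.nan
                if undefined
                else _dprime(
                    len(go),
                    int(go["responded_yes"].sum()),
                    len(nogo),
                    int(nogo["responded_yes"].sum()),
                )
            )
        else:
            raise ValueError(f"unknown measure {measure!r}")
        rows.append(
            dict(zip(keys, key)) | {"sensitivity": value, "n_nogo": len(nogo), "undefined": undefined}
        )
    return pd.DataFrame(rows)
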