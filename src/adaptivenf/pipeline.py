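"""Per-subject and cohort-level conveniences tying the modules together.

These helpers run the canonical chain for one synthetic subject — training
run, z-scoring, classifier fit, closed-loop feedback run, regulation GLM —
and assemble the long-format tables the group mixed models consume.

Sign convention for regulation: the regulation GLM regresses the hyperplane
distance on HRF-convolved 0/1 block boxcars, so good regulation shows as a
positive attend-face beta and a negative attend-word beta. The
instruction-consistent regulation score reported per (subject, instruction)
is therefore the beta multiplied by the instruction's label (+1 face,
-1 word), so that higher always means better correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis, decode, neurofeedback, preproc, synthdata, taskdesign


@dataclass
class SubjectResult:
    """Everything the group analyses need from one simulated subject."""

    spec: synthdata.SyntheticSubjectSpec
    model: decode.ClassifierModel
    cv_accuracy: dict  # valence name -> proportion
    sensitivity: dict  # valence name -> no-go accuracy
    regulation: pd.DataFrame  # columns: run, instruction, regulation_beta
    session_traces: list


def train_subject(
    spec: synthdata.SyntheticSubjectSpec,
    design: taskdesign.RunDesign,
    n_runs: int = 2,
):
    """Simulate the training runs and fit the subject's brain-state SVM.

    Features are z-scored per run and concatenated across runs (two training
    runs by default) before fitting; motion-censored TRs are excluded.
    Returns the model plus the per-run raw features, labels, block ids,
    censor keeps, and the pooled response log.
    """
    feats_z, feats_raw, labels, block_ids, keeps, logs = [], [], [], [], [], []
    for run in range(n_runs):
        volumes, motion, log = synthdata.generate_run(spec, design, run_index=run)
        fd = preproc.framewise_displacement(
            preproc.MotionTrace(motion.values, design.tr_seconds)
        )
        censor = preproc.censor_mask(fd)
        raw = volumes.to_features()
        feats_raw.append(raw)
        feats_z.append(preproc.normalize(raw, "zscore", censor=censor).values)
        labels.append(design.tr_labels)
        bid = design.block_index_per_tr()
        block_ids.append(np.where(bid >= 0, bid + run * len(design.blocks), -1))
        keeps.append(censor.keep)
        logs.append(log.trials)
    X = np.vstack(feats_z)
    y = np.concatenate(labels)
    keep = np.concatenate(keeps)
    model = decode.train_classifier(X, y, keep=keep)
    pooled_log = taskdesign.ResponseLog(trials=pd.concat(logs, ignore_index=True))
    return model, np.vstack(feats_raw), y, np.concatenate(block_ids), keep, pooled_log


def feedback_session(
    spec: synthdata.SyntheticSubjectSpec,
    model: decode.ClassifierModel,
    design: taskdesign.RunDesign,
    seed: int = 0,
) -> tuple[neurofeedback.SessionTrace, analysis.RegulationResult]:
    """Run one closed-loop feedback run and fit its regulation GLM."""
    trace = neurofeedback.run_closed_loop(spec, model, design, seed=seed)
    dm = analysis.build_design(design)
    hd = trace.hd_trace()
    reg = analysis.regulation_betas(hd.values, dm, valid=hd.valid)
    return trace, reg


def run_subject(
    spec: synthdata.SyntheticSubjectSpec,
    training_design: taskdesign.RunDesign,
    feedback_design: taskdesign.RunDesign,
    n_feedback_runs: int = 1,
) -> SubjectResult:
    """Full desk-scale session for one subject.

    Two training runs feed the classifier (features z-scored per run and
    concatenated); cross-validated accuracy and no-go sensitivity are
    computed per word valence; ``n_feedback_runs`` closed-loop runs yield
    instruction-consistent regulation scores.
    """
    model, feats, labels, block_ids, keep, log = train_subject(spec, training_design)

    valence = np.tile(training_design.tr_valence, 2)
    cv_accuracy = {
        name: decode.crossvalidate_blocks(
            feats,
            labels,
            block_ids,
            valence=valence,
            valence_filter=name,
        )
        for name in ("trauma", "neutral")
    }
    sens = taskdesign.score_sensitivity(log, by="condition")
    sensitivity = {
        taskdesign.VALENCE_NAMES[v]: float(
            sens.loc[sens["valence"] == v, "sensitivity"].mean()
        )
        for v in (taskdesign.TRAUMA, taskdesign.NEUTRAL)
    }

    reg_rows = []
    traces = []
    for run in range(n_feedback_runs):
        trace, reg = feedback_session(spec, model, feedback_design, seed=run)
        traces.append(trace)
        for instr, name in ((1, "attend_face"), (-1, "attend_word")):
            reg_rows.append(
                {
                    "run": run,
                    "instruction": instr,
                    "regulation_beta": instr * float(reg.betas[name]),
                }
            )
    return SubjectResult(
        spec=spec,
        model=model,
        cv_accuracy=cv_accuracy,
        sensitivity=sensitivity,
        regulation=pd.DataFrame(reg_rows),
        session_traces=traces,
    )


def cohort_tables(
    results: list[SubjectResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format tables for the group mixed models.

    Returns ``(training, regulation)``: training rows are
    (subject, group, valence, cv_accuracy, sensitivity, age, education);
    regulation rows are (subject, group, run, attention, regulation_beta,
    age, education). Contrast codes: group PTSD +1 / control -1, valence
    trauma +1 / neutral -1, attention face +1 / word -1.
    """
    train_rows, reg_rows = [], []
    for res in results:
        s = res.spec
        base = {"subject": s.subject_id, "group": s.group, "age": s.age, "education": s.education}
        for vname, vcode in (("trauma", 1), ("neutral", -1)):
            train_rows.append(
                base
                | {
                    "valence": vcode,
                    "cv_accuracy": res.cv_accuracy[vname],
                    "sensitivity": res.sensitivity[vname],
                }
            )
        for _, row in res.regulation.iterrows():
            reg_rows.append(
                base
                | {
                    "run": int(row["run"]),
                    "attention": int(row["instruction"]),
                    "regulation_beta": float(row["regulation_beta"]),
                }
            )
    return pd.DataFrame(train_rows), pd.DataFrame(reg_rows)


def simulate_cohort(
    n_ptsd: int = 10,
    n_control: int = 9,
    seed: int = 0,
    n_feedback_runs: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort and return the two group-analysis tables."""
    specs = synthdata.generate_cohort(n_ptsd, n_control, seed=seed)
    training = taskdesign.build_training_design(seed=seed)
    feedback = taskdesign.build_feedback_design(seed=seed + 1)
    results = [
        run_subject(spec, training, feedback, n_feedback_runs=n_feedback_runs)
        for spec in specs
    ]
    return cohort_tables(results)
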