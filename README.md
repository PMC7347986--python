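# adaptivenf

A desk-scale, fully tested re-implementation of an adaptive real-time fMRI
neurofeedback (A-NF) paradigm and its analysis chain, aimed at researchers
who want to prototype, verify, or teach closed-loop decoded-neurofeedback
methods without a scanner.

In the paradigm this package models, participants (a PTSD group and a
control group) view composite word-on-face stimuli in 30-trial blocks and
are instructed to attend either to the word or to the face. A whole-brain
SVM (RBF kernel, C = 1) is trained on z-scored gray-matter voxel time
courses from two block-design training runs to separate the two attentional
brain states (labels attend-face = +1, attend-word = −1; rest TRs censored).
During feedback runs every new volume is incrementally detrended and
z-scored against the accumulating run data (after a 20-TR warmup), scored by
the classifier to give a signed hyperplane distance (HD), and mapped to
stimulus opacity:

    opacity = 0.17 + 0.66 · σ(HD),  σ(x) = 1 / (1 + e^(−x))

so that the target stimulus fades as the brain state drifts away from the
instructed state. Opacities are temporally smoothed (mean of the current and
previous two values, starting at the fourth value of a block), quantized to
the 0–255 alpha range, and applied to the next TR's two trials; each block
starts balanced at 50/50. The offline chain covers framewise-displacement
censoring (FD > 0.4 mm plus the following TR, isolated-TR and 50%-run
rules), 26-column Volterra motion/CSF/WM nuisance sets, leave-one-block-out
cross-validated decoding accuracy, Haufe forward-encoding maps
A = Cov(X)w / var(Xw), HD-on-design regulation GLMs with the canonical
double-gamma HRF, group-level linear mixed models, and cluster-extent
thresholding (uncorrected p < 0.001, ≥ 13 face-connected voxels).

No imaging data ship with the package: a generative `synthdata` module
simulates subjects whose latent attention state follows instructions with a
compliance weight, is attenuated during trauma-word blocks in the PTSD
group, and responds to the feedback opacity — closing the loop entirely in
software.

## Worked example

```python
from adaptivenf import pipeline, synthdata, taskdesign

training = taskdesign.build_training_design(tr_seconds=2.0, seed=0)
feedback = taskdesign.build_feedback_design(tr_seconds=2.0, seed=1)
spec = synthdata.make_subject_spec("control", seed=7, overrides={})

res = pipeline.run_subject(spec, training, feedback)
print(f"CV accuracy (trauma blocks):  {res.cv_accuracy['trauma']:.3f}")
print(f"CV accuracy (neutral blocks): {res.cv_accuracy['neutral']:.3f}")
print(f"No-go sensitivity (trauma):   {res.sensitivity['trauma']:.3f}")
task = res.session_traces[0].frame.query("instruction != 'rest'")
print(f"Mean target opacity:          {task['target_opacity'].mean():.3f}")
```

prints

```
CV accuracy (trauma blocks):  0.967
CV accuracy (neutral blocks): 0.933
No-go sensitivity (trauma):   0.722
Mean target opacity:          0.578
```

Cross-validated accuracy well above chance shows the classifier separates
the two attentional states of this simulated subject; the no-go sensitivity
is the proportion of rare no-go trials with a correctly withheld response;
and a mean target opacity above 0.5 means the closed loop rewarded the
subject's (compliant) brain states by keeping the attended stimulus visible.
`res.regulation` additionally holds the instruction-consistent regulation
betas from regressing the HD trace on the HRF-convolved task design.

Cohort-level analyses mirror the group studies: `pipeline.simulate_cohort()`
simulates 10 PTSD + 9 control subjects end to end and returns long-format
tables for `analysis.fit_group_lme`, e.g.

```python
train, reg = pipeline.simulate_cohort(seed=0)
res = analysis.fit_group_lme(
    reg, "regulation_beta ~ attention * group + age + education",
    re_formula="~attention",
)
```

## Layout

- `adaptivenf.taskdesign` — block/trial designs, event tables, sensitivity scoring
- `adaptivenf.synthdata` — synthetic subjects, runs, motion, behavior
- `adaptivenf.preproc` — FD, censoring, Volterra nuisance, normalization, smoothing
- `adaptivenf.decode` — SVM training, HD prediction, block-wise CV, forward encoding
- `adaptivenf.neurofeedback` — the real-time loop and opacity transform chain
- `adaptivenf.analysis` — HRF, design matrices, GLMs, group LMEs, cluster thresholding
- `adaptivenf.pipeline` — per-subject and cohort orchestration
- `adaptivenf.io` — NIfTI / TSV / motion-text readers and writers

See `docs/methods.md` for the generative model, parameter choices, and
limitations.
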