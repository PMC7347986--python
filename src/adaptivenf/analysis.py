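"""Downstream statistics for the neurofeedback pipeline.

Covers the canonical double-gamma HRF, HRF-convolved block design matrices
(optionally with opacity modulators), ordinary-least-squares regulation betas
for hyperplane-distance traces, voxelwise GLMs, group-level linear
mixed-effects models, and cluster-extent thresholding of t-maps.

Contrast coding throughout matches the group analyses: Group PTSD = +1 vs.
control = -1, Attention attend-to-face = +1 vs. attend-to-word = -1, Valence
trauma = +1 vs. neutral = -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preproc import CensorMask, NuisanceMatrix
from .taskdesign import ATTEND_FACE, ATTEND_WORD, RunDesign

HRF_PEAK_SHAPE = 6.0
HRF_UNDERSHOOT_SHAPE = 16.0
HRF_SCALE = 1.0
HRF_UNDERSHOOT_RATIO = 6.0
HRF_DURATION_S = 32.0


def canonical_hrf(tr_seconds: float, duration_s: float = HRF_DURATION_S) -> np.ndarray:
    """Canonical double-gamma HRF sampled on the TR grid, peak-normalized.

    The kernel is gammaPDF(t; shape 6, scale 1) minus one sixth of
    gammaPDF(t; shape 16, scale 1), truncated at 32 s. Peak ~5 s, undershoot
    ~15 s.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0, duration_s + 1e-9, tr_seconds)
    h = stats.gamma.pdf(t, HRF_PEAK_SHAPE, scale=HRF_SCALE) - stats.gamma.pdf(
        t, HRF_UNDERSHOOT_SHAPE, scale=HRF_SCALE
    ) / HRF_UNDERSHOOT_RATIO
    return h / h.max()


def hrf_convolve(x: np.ndarray, tr_seconds: float) -> np.ndarray:
    """Causally convolve a per-TR time course with the canonical HRF."""
    h = canonical_hrf(tr_seconds)
    return np.convolve(x, h)[: len(x)]


@dataclass(frozen=True)
class DesignMatrix:
    """TR x regressor matrix with names, the HRF used, and the censor mask."""

    values: np.ndarray
    names: tuple[str, ...]
    tr_seconds: float
    keep: np.ndarray  # boolean rows to include in fits

    def __post_init__(self):
        if self.values.shape[1] != len(self.names):
            raise ValueError("design column count does not match names")
        if self.values.shape[0] != len(self.keep):
            raise ValueError("keep mask length does not match design rows")

    @property
    def task_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n != "intercept")


def build_design(
    design: RunDesign,
    opacity: np.ndarray | None = None,
    censor: CensorMask | None = None,
) -> DesignMatrix:
    """Build the HRF-convolved design matrix for one run.

    Two block regressors (attend-to-word, attend-to-face boxcars convolved
    with the canonical HRF) plus an intercept. If a per-TR target-stimulus
    ``opacity`` trace is given, two parametric modulator columns are added:
    instruction x target opacity, mean-centered within the instruction's
    blocks before convolution (centering decorrelates the modulator from the
    block main effect). Censored rows are flagged for exclusion from fits.
    """
    labels = design.tr_labels
    n = design.n_trs
    keep = censor.keep.copy() if censor is not None else np.ones(n, dtype=bool)
    if not keep.any():
        raise ValueError("all TRs censored; cannot build a design")
    tr = design.tr_seconds

    cols = [np.ones(n)]
    names = ["intercept"]
    for instr, name in ((ATTEND_WORD, "attend_word"), (ATTEND_FACE, "attend_face")):
        boxcar = (labels == instr).astype(float)
        cols.append(hrf_convolve(boxcar, tr))
        names.append(name)

    if opacity is not None:
        opacity = np.asarray(opacity, dtype=float)
        if len(opacity) != n:
            raise ValueError(f"opacity length {len(opacity)} != design TRs {n}")
        for instr, name in (
            (ATTEND_WORD, "attend_word_x_opacity"),
            (ATTEND_FACE, "attend_face_x_opacity"),
        ):
            on = labels == instr
            mod = np.zeros(n)
            if on.any():
                mod[on] = opacity[on] - opacity[on].mean()
            cols.append(hrf_convolve(mod, tr))
            names.append(name)

    return DesignMatrix(
        values=np.column_stack(cols), names=tuple(names), tr_seconds=tr, keep=keep
    )


@dataclass(frozen=True)
class RegulationResult:
    """OLS betas of an HD trace on the task design: the regulation estimate.

    A higher block-regressor beta means the observed brain state tracked the
    instructed state more closely.
    """

    betas: pd.Series
    stderr: pd.Series
    residual_variance: float
    df: int


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        bad = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns include {bad}")


def regulation_betas(hd: np.ndarray, dm: DesignMatrix, valid: np.ndarray | None = None) -> RegulationResult:
    """Regress a per-TR hyperplane-distance trace onto the task design.

    Censored TRs (and TRs flagged invalid in the trace, e.g. warmup) are
    dropped; ordinary least squares on the rest.
    """
    hd = np.asarray(hd, dtype=float)
    rows = dm.keep.copy()
    if valid is not None:
        rows &= np.asarray(valid, dtype=bool)
    rows &= np.isfinite(hd)
    X = dm.values[rows]
    y = hd[rows]
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few valid TRs for the regulation fit")
    _check_rank(X, dm.names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = float(resid @ resid / df)
    cov = s2 * np.linalg.inv(X.T @ X)
    return RegulationResult(
        betas=pd.Series(beta, index=list(dm.names)),
        stderr=pd.Series(np.sqrt(np.diag(cov)), index=list(dm.names)),
        residual_variance=s2,
        df=df,
    )


def voxelwise_glm(
    features: np.ndarray,
    dm: DesignMatrix,
    nuisance: NuisanceMatrix | None = None,
    censor: CensorMask | None = None,
) -> pd.DataFrame:
    """Per-voxel OLS of a TR x voxel matrix on task plus nuisance columns.

    Returns a DataFrame with one row per task regressor holding beta, t and
    two-sided p arrays (each a voxel vector). Censored rows are excluded
    before fitting, so altering data at censored TRs cannot change the betas.
    """
    y = np.asarray(features, dtype=float)
    if y.shape[0] != dm.values.shape[0]:
        raise ValueError("feature rows do not match design rows")
    rows = dm.keep.copy()
    if censor is not None:
        rows &= censor.keep
    X = dm.values
    names = list(dm.names)
    if nuisance is not None:
        if nuisance.values.shape[0] != X.shape[0]:
            raise ValueError("nuisance rows do not match design rows")
        X = np.column_stack([X, nuisance.values])
        names += list(nuisance.names)
    X = X[rows]
    Y = y[rows]
    _check_rank(X, tuple(names))
    pinv = np.linalg.pinv(X)
    B = pinv @ Y  # regressors x voxels
    resid = Y - X @ B
    df = X.shape[0] - X.shape[1]
    s2 = (resid**2).sum(axis=0) / df
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    se = np.sqrt(np.outer(xtx_inv_diag, s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, B / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    out = []
    for i, name in enumerate(names):
        if name == "intercept" or (nuisance is not None and name in nuisance.names):
            continue
        out.append({"regressor": name, "beta": B[i], "t": tvals[i], "p": pvals[i], "df": df})
    return pd.DataFrame(out)


@dataclass(frozen=True)
class GroupModelResult:
    """Fixed-effect table from a mixed model plus bookkeeping."""

    fixed_effects: pd.DataFrame  # name, estimate, se, t, p
    random_structure: str
    converged: bool
    simplified: bool


def fit_group_lme(
    table: pd.DataFrame,
    formula: str,
    groups: str = "subject",
    re_formula: str | None = None,
) -> GroupModelResult:
    """REML linear mixed model with by-subject random effects.

    ``formula`` is a patsy fixed-effects formula (e.g.
    ``"sensitivity ~ attention * valence * group + age + education"``);
    ``re_formula`` gives the by-subject random slopes (e.g.
    ``"~attention * valence"``). If the full random structure fails to
    converge, it is simplified stepwise (slopes -> intercept only), and the
    result is flagged.
    """
    import re as _re

    import statsmodels.formula.api as smf

    # constant covariates make the fixed design singular; drop such
    # standalone terms so the fit equals the covariate-free model
    lhs, rhs = formula.split("~")
    terms = [t.strip() for t in rhs.split("+")]
    kept_terms = []
    for term in terms:
        if _re.fullmatch(r"\w+", term) and term in table.columns:
            if pd.api.types.is_numeric_dtype(table[term]) and table[term].nunique() == 1:
                continue
        kept_terms.append(term)
    formula = f"{lhs.strip()} ~ {' + '.join(kept_terms)}"

    attempts = [re_formula]
    if re_formula not in (None, "~1", "1"):
        terms = [t.strip() for t in re_formula.lstrip("~").split("*")]
        if len(terms) > 1:
            attempts.append("~" + " + ".join(terms))
        attempts.append("~1")
    else:
        attempts = [re_formula or "~1"]

    last_err = None
    for i, rf in enumerate(attempts):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, table, groups=table[groups], re_formula=rf)
                fit = model.fit(reml=True)
            if np.all(np.isfinite(fit.bse_fe)):
                fe = pd.DataFrame(
                    {
                        "name": fit.fe_params.index,
                        "estimate": fit.fe_params.values,
                        "se": fit.bse_fe.values,
                        "t": fit.tvalues[: len(fit.fe_params)].values,
                        "p": fit.pvalues[: len(fit.fe_params)].values,
                    }
                )
                return GroupModelResult(
                    fixed_effects=fe,
                    random_structure=rf or "~1",
                    converged=bool(fit.converged),
                    simplified=i > 0,
                )
        except Exception as err:  # noqa: BLE001 - fall through to simpler structure
            last_err = err
    raise RuntimeError(f"mixed model failed to converge even with random intercept only: {last_err}")


@dataclass(frozen=True)
class ClusterTable:
    """Supra-threshold clusters of a t-map: size, peak, center of mass, sign."""

    clusters: pd.DataFrame
    t_critical: float
    extent: int

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_threshold(
    stat_map: np.ndarray,
    df: int,
    p_uncorrected: float = 0.001,
    extent: int = 13,
    mask: np.ndarray | None = None,
) -> ClusterTable:
    """Two-sided cluster-extent thresholding of a 3D t-map.

    Voxels with |t| above the two-sided critical value at ``p_uncorrected``
    form connected components under face adjacency (nearest neighbour = 1);
    components of ``extent`` or more voxels are reported with size, peak
    statistic, peak coordinate and center of mass, positive and negative
    clusters labeled separately.
    """
    if extent < 1:
        raise ValueError("extent must be >= 1")
    t = np.asarray(stat_map, dtype=float)
    if t.ndim != 3:
        raise ValueError("stat_map must be 3D")
    t_crit = float(stats.t.isf(p_uncorrected / 2, df))
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    rows = []
    for sign in (+1, -1):
        supra = (sign * t) > t_crit
        if mask is not None:
            supra &= mask.astype(bool)
        labeled, n_comp = ndimage.label(supra, structure=structure)
        for comp in range(1, n_comp + 1):
            voxels = labeled == comp
            size = int(voxels.sum())
            if size < extent:
                continue
            vals = np.where(voxels, t, 0.0)
            flat_peak = np.argmax(sign * vals)
            peak = np.unravel_index(flat_peak, t.shape)
            com = ndimage.center_of_mass(voxels)
            rows.append(
                {
                    "sign": sign,
                    "size": size,
                    "peak_t": float(t[peak]),
                    "peak_x": peak[0],
                    "peak_y": peak[1],
                    "peak_z": peak[2],
                    "com_x": com[0],
                    "com_y": com[1],
                    "com_z": com[2],
                }
            )
    clusters = pd.DataFrame(
        rows,
        columns=["sign", "size", "peak_t", "peak_x", "peak_y", "peak_z", "com_x", "com_y", "com_z"],
    )
    if len(clusters):
        clusters = clusters.sort_values("size", ascending=False, ignore_index=True)
    return ClusterTable(clusters=clusters, t_critical=t_crit, extent=extent)
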