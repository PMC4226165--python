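"""Linkage statistics: correlation matrices, standardized and stepwise
regression, within-subject ANOVA with Greenhouse-Geisser correction, and
ROI-level brain-covariate analyses.

These are the tools that connect the behavioral exploration index to the
autonomic change scores and to regional brain activity: Pearson
correlation matrices over subjects, a standardized multiple regression
solvable directly from a correlation matrix (normal equations on
z-scores), p-value-driven stepwise selection, balanced fully-repeated
ANOVA (2- or 3-way within-subject) with Greenhouse-Geisser epsilon and
partial eta squared, and per-ROI correlation/connectivity screens that
stand in for voxelwise covariate maps at the region level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pearson correlation matrix


@dataclass
class CorrelationMatrix:
    labels: list[str]
    r: np.ndarray
    p: np.ndarray
    n: int

    def to_frame(self, which: str = "r") -> pd.DataFrame:
        m = self.r if which == "r" else self.p
        return pd.DataFrame(m, index=self.labels, columns=self.labels)


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r via the t transform with n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlations over subjects (rows) x variables
    (columns), with two-sided p-values."""
    if table.isna().any().any():
        raise StatsError("missing values in correlation input")
    n = len(table)
    if n < 3:
        raise StatsError("need at least 3 subjects for correlations")
    values = table.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        col = table.columns[int(np.argmin(sd))]
        raise StatsError(f"zero-variance column: {col!r}")
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    p = pearson_p(r, n)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(list(table.columns), r, p, n)


# ---------------------------------------------------------------------------
# Standardized regression from a correlation matrix


@dataclass
class RegressionResult:
    predictors: list[str]
    standardized_betas: np.ndarray
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_model: float
    p_values: np.ndarray
    selection_trace: list[dict] = field(default_factory=list)


def standardized_ols_from_correlations(r_yx: np.ndarray, R_xx: np.ndarray,
                                       n: int,
                                       predictors: list[str] | None = None
                                       ) -> RegressionResult:
    """Solve the standardized normal equations beta = R_xx^-1 r_yx.

    Produces exactly the coefficients OLS would give on z-scored raw data
    whose sample correlations equal the inputs.  R^2 = r_yx' beta;
    adjusted R^2, the overall F with (k, n-k-1) df, and per-coefficient
    t-based p-values follow the standard formulas.
    """
    r_yx = np.atleast_1d(np.asarray(r_yx, dtype=float))
    R_xx = np.atleast_2d(np.asarray(R_xx, dtype=float))
    k = r_yx.size
    if R_xx.shape != (k, k):
        raise StatsError("R_xx shape does not match r_yx length")
    cond = np.linalg.cond(R_xx)
    if not np.isfinite(cond) or cond > 1e12:
        raise StatsError("predictor correlation matrix is singular (collinearity)")
    betas = np.linalg.solve(R_xx, r_yx)
    r2 = float(r_yx @ betas)
    df2 = n - k - 1
    if df2 <= 0:
        raise StatsError("not enough subjects for the requested model")
    adj = 1.0 - (1.0 - r2) * (n - 1) / df2
    if r2 >= 1.0:
        f = np.inf
    else:
        f = (r2 / k) / ((1.0 - r2) / df2)
    p_model = float(sps.f.sf(f, k, df2)) if np.isfinite(f) else 0.0
    # per-coefficient t: se(beta_j) = sqrt((1-R^2)/df2 * [R_xx^-1]_jj)
    inv_diag = np.diag(np.linalg.inv(R_xx))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(1.0 - r2, 0.0) / df2 * inv_diag)
        t = np.where(se > 0, betas / se, np.inf * np.sign(betas))
    p_coef = 2.0 * sps.t.sf(np.abs(t), df2)
    return RegressionResult(
        predictors=list(predictors) if predictors is not None
        else [f"x{i + 1}" for i in range(k)],
        standardized_betas=betas, r_squared=r2, adjusted_r_squared=float(adj),
        f_statistic=float(f), df=(k, df2), p_model=p_model, p_values=p_coef,
    )


def standardized_ols(y: np.ndarray, X: pd.DataFrame) -> RegressionResult:
    """Standardized regression from raw data (via the sample correlations)."""
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    full = np.column_stack([y, X.to_numpy(dtype=float)])
    R = np.corrcoef(full, rowvar=False)
    return standardized_ols_from_correlations(R[0, 1:], R[1:, 1:], len(y),
                                              predictors=names)


# ---------------------------------------------------------------------------
# Stepwise regression


def _ols_pvalues(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient estimates and two-sided p-values for OLS with intercept."""
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - k - 1
    if df <= 0:
        raise StatsError("not enough observations for OLS fit")
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return beta[1:], p[1:]


def stepwise_regression(y: np.ndarray, X: pd.DataFrame,
                        p_enter: float = 0.05,
                        p_remove: float = 0.10) -> RegressionResult:
    """Forward selection with backward removal on coefficient p-values.

    At each step the candidate with the smallest entry p-value joins the
    model if that p-value is below ``p_enter``; after each entry, any
    included variable whose p-value has risen above ``p_remove`` leaves.
    An empty model (no candidate meets ``p_enter``) is a valid result.
    The selection trace records each entering/leaving variable.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    data = {name: X[name].to_numpy(dtype=float) for name in names}
    included: list[str] = []
    trace: list[dict] = []
    while True:
        changed = False
        candidates = [v for v in names if v not in included]
        if candidates:
            best_p, best_var = np.inf, None
            for var in candidates:
                cols = included + [var]
                try:
                    _, pvals = _ols_pvalues(y, np.column_stack([data[v] for v in cols]))
                except StatsError:
                    continue
                if pvals[-1] < best_p:
                    best_p, best_var = pvals[-1], var
            if best_var is not None and best_p < p_enter:
                included.append(best_var)
                trace.append({"step": len(trace) + 1, "action": "enter",
                              "variable": best_var, "p": float(best_p)})
                changed = True
        if included:
            _, pvals = _ols_pvalues(y, np.column_stack([data[v] for v in included]))
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                var = included.pop(worst)
                trace.append({"step": len(trace) + 1, "action": "remove",
                              "variable": var, "p": float(pvals[worst])})
                changed = True
        if not changed:
            break
    if not included:
        return RegressionResult(predictors=[], standardized_betas=np.array([]),
                                r_squared=0.0, adjusted_r_squared=0.0,
                                f_statistic=np.nan, df=(0, len(y) - 1),
                                p_model=np.nan, p_values=np.array([]),
                                selection_trace=trace)
    result = standardized_ols(y, X[included])
    result.selection_trace = trace
    return result


# ---------------------------------------------------------------------------
# Repeated-measures (fully within-subject) ANOVA


@dataclass
class AnovaEffect:
    effect: str
    F: float
    df: tuple[float, float]
    epsilon: float
    p_gg: float
    p_uncorrected: float
    partial_eta_squared: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    effects: list[AnovaEffect]

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "effect": e.effect, "F": e.F, "df1": e.df[0], "df2": e.df[1],
            "epsilon": e.epsilon, "p_gg": e.p_gg, "p": e.p_uncorrected,
            "partial_eta_sq": e.partial_eta_squared,
        } for e in self.effects])


def _pivot_cells(data: pd.DataFrame, dv: str, subject: str,
                 within: list[str]) -> tuple[np.ndarray, list[list]]:
    """Arrange a long table as an array [subject, f1, f2, ...]; error on
    missing cells naming the subject and cell."""
    subjects = sorted(data[subject].unique())
    levels = [sorted(data[f].unique()) for f in within]
    shape = (len(subjects),) + tuple(len(lv) for lv in levels)
    arr = np.full(shape, np.nan)
    index = {s: i for i, s in enumerate(subjects)}
    level_index = [{lv: i for i, lv in enumerate(lvs)} for lvs in levels]
    for row in data.itertuples(index=False):
        d = row._asdict()
        pos = (index[d[subject]],) + tuple(
            level_index[i][d[f]] for i, f in enumerate(within))
        arr[pos] = d[dv]
    if np.isnan(arr).any():
        pos = np.argwhere(np.isnan(arr))[0]
        cell = {f: levels[i][pos[i + 1]] for i, f in enumerate(within)}
        raise StatsError(
            f"missing cell for subject {subjects[pos[0]]!r}: {cell}")
    return arr, levels


def _effect_term(arr: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion estimate of the effect on the given axes,
    broadcast to the full array shape."""
    all_axes = tuple(range(arr.ndim))
    term = np.zeros_like(arr)
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            other = tuple(a for a in all_axes if a not in sub)
            m = arr.mean(axis=other, keepdims=True) if other else arr
            term = term + ((-1) ** (len(axes) - r)) * m
    return term


def gg_epsilon(arr: np.ndarray, axes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for a within-subject effect.

    ``arr`` is [subject, f1, ...]; the effect's orthonormal contrast is
    the Kronecker product of per-factor Helmert contrasts applied to the
    subject x effect-cells marginal means.  epsilon = tr(S)^2 / (d * sum S^2)
    with S the sample covariance of the contrast scores; equals 1 exactly
    for a single-df (2-level) effect.
    """
    other = tuple(a for a in range(1, arr.ndim) if a not in axes)
    marg = arr.mean(axis=other) if other else arr
    # marg axes: subject then the effect factors, in axis order
    C = np.ones((1, 1))
    for ax in sorted(axes):
        m = arr.shape[ax]
        H = helmert(m, full=True)[1:]  # orthonormal rows, constant removed
        C = np.kron(C, H)
    flat = marg.reshape(marg.shape[0], -1)
    scores = flat @ C.T
    d = scores.shape[1]
    if d == 1:
        return 1.0
    S = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(S)
    denom = d * np.sum(S * S)
    if denom == 0:
        return 1.0
    return float(np.clip(tr * tr / denom, 1.0 / d, 1.0))


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> AnovaResult:
    """Balanced fully repeated-measures ANOVA (any number of within
    factors; the study designs are 2-way condition x block for behavior
    and 3-way condition x period x block for autonomic panels).

    Each effect is tested against its interaction with subjects
    (univariate mixed-model approach); Greenhouse-Geisser epsilon adjusts
    the df of effects with more than one numerator df.  Effects with zero
    sum of squares report F = 0.
    """
    arr, levels = _pivot_cells(data, dv, subject, within)
    n_subj = arr.shape[0]
    if n_subj < 2:
        raise StatsError("need at least 2 subjects")
    factor_axes = list(range(1, arr.ndim))
    effects = []
    for r in range(1, len(factor_axes) + 1):
        for combo in itertools.combinations(factor_axes, r):
            name = " x ".join(within[a - 1] for a in combo)
            term = _effect_term(arr, combo)
            err = _effect_term(arr, combo + (0,))
            ss_eff = float((term ** 2).sum())
            ss_err = float((err ** 2).sum())
            df1 = int(np.prod([arr.shape[a] - 1 for a in combo]))
            df2 = df1 * (n_subj - 1)
            if ss_eff <= 1e-12 * max(ss_err, 1.0):
                F, p = 0.0, 1.0
            elif ss_err == 0:
                F, p = np.inf, 0.0
            else:
                F = (ss_eff / df1) / (ss_err / df2)
                p = float(sps.f.sf(F, df1, df2))
            eps = gg_epsilon(arr, combo)
            p_gg = (float(sps.f.sf(F, eps * df1, eps * df2))
                    if np.isfinite(F) and F > 0 else p)
            peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            effects.append(AnovaEffect(
                effect=name, F=float(F), df=(df1, df2), epsilon=eps,
                p_gg=p_gg, p_uncorrected=p,
                partial_eta_squared=float(peta),
                ss_effect=ss_eff, ss_error=ss_err))
    return AnovaResult(effects)


# ---------------------------------------------------------------------------
# ROI-level brain-covariate analyses


@dataclass
class RoiCorrelation:
    roi_label: str
    r: float
    p: float
    sign: int
    flagged: bool


def _align_roi(roi: pd.DataFrame, covariate: pd.Series) -> tuple[pd.DataFrame, np.ndarray]:
    if not roi.index.equals(covariate.index):
        if set(roi.index) != set(covariate.index):
            raise StatsError("subject mismatch between ROI table and covariate")
        covariate = covariate.reindex(roi.index)
    return roi, covariate.to_numpy(dtype=float)


def roi_covariate_correlation(roi: pd.DataFrame, covariate: pd.Series,
                              alpha: float = 0.001) -> list[RoiCorrelation]:
    """Across-subject Pearson correlation of each ROI with a covariate.

    ``roi`` is subjects x ROI labels (index = subject ids); ROIs whose
    two-sided p falls below ``alpha`` are flagged with their sign.  This
    is the region-level analogue of a voxelwise covariate correlation map
    thresholded at an uncorrected alpha.
    """
    roi, cov = _align_roi(roi, covariate)
    n = len(roi)
    out = []
    for label in roi.columns:
        vals = roi[label].to_numpy(dtype=float)
        r = float(np.corrcoef(vals, cov)[0, 1])
        p = float(pearson_p(np.array(r), n))
        out.append(RoiCorrelation(roi_label=str(label), r=r, p=p,
                                  sign=int(np.sign(r)), flagged=p < alpha))
    return out


def seed_connectivity(roi: pd.DataFrame, seed_label: str,
                      alpha: float = 0.001) -> list[RoiCorrelation]:
    """Across-subject correlation of one ROI (the seed) with every other."""
    if seed_label not in roi.columns:
        raise StatsError(f"unknown seed ROI: {seed_label!r}")
    seed = roi[seed_label]
    others = roi.drop(columns=[seed_label])
    return roi_covariate_correlation(others, seed, alpha=alpha)
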