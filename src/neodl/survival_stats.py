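"""Survival statistics: Cox fits, feature screening, KM/log-rank, baselines.

Single proportional-hazards fits (univariate and covariate-adjusted) are
delegated to lifelines with Efron tie handling. Valid-feature screening has
to run one univariate fit per vocabulary entry (thousands per cohort), so it
uses an in-package Newton solver of the univariate Efron partial likelihood
vectorized across features; tests pin it against lifelines feature-by-feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored overall survival: time in days, event 1=death 0=censored."""

    time: np.ndarray
    event: np.ndarray
    patient_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValueError("times must be finite and non-negative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicators must be 0/1")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        if self.patient_ids is not None and len(self.patient_ids) != t.size:
            raise ValueError("patient_ids length mismatch")

    def __len__(self) -> int:
        return self.time.size

    @classmethod
    def from_cohort(cls, cohort, patients: Sequence[str] | None = None) -> "SurvivalData":
        cf = cohort.clinical_frame()
        if patients is not None:
            cf = cf.loc[list(patients)]
        return cls(cf["os_days"].to_numpy(), cf["os_event"].to_numpy(),
                   tuple(cf.index))

    def subset(self, idx) -> "SurvivalData":
        ids = tuple(np.asarray(self.patient_ids)[idx]) if self.patient_ids else None
        return SurvivalData(self.time[idx], self.event[idx], ids)

    def _check_fit(self) -> None:
        if len(self) < 2:
            raise ValueError("need at least two subjects")
        if self.event.sum() == 0:
            raise ValueError("need at least one event")


@dataclass(frozen=True)
class CoxFit:
    beta: float
    hr: float
    p: float
    ci95: tuple[float, float]
    n: int
    converged: bool
    se: float = float("nan")


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p: float


# ---------------------------------------------------------------------------
# single Cox fits (lifelines)
# ---------------------------------------------------------------------------

def _cox_frame(survival: SurvivalData, columns: dict[str, np.ndarray]) -> pd.DataFrame:
    df = pd.DataFrame({"T": survival.time, "E": survival.event})
    for k, v in columns.items():
        df[k] = np.asarray(v, dtype=float)
    return df


def cox_univariate(values, survival: SurvivalData) -> CoxFit:
    """Univariate Cox PH fit (Efron ties, Wald p) of one feature."""
    survival._check_fit()
    x = np.asarray(values, dtype=float)
    if x.shape != survival.time.shape:
        raise ValueError("feature values must align with survival data")
    if not np.isfinite(x).all():
        raise ValueError("feature values must be finite")
    if np.ptp(x) == 0:
        return CoxFit(np.nan, np.nan, np.nan, (np.nan, np.nan), len(survival), False)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(_cox_frame(survival, {"x": x}), duration_col="T", event_col="E")
    except (ConvergenceError, ValueError):
        return CoxFit(np.nan, np.nan, np.nan, (np.nan, np.nan), len(survival), False)
    s = cph.summary.loc["x"]
    return CoxFit(
        beta=float(s["coef"]), hr=float(np.exp(s["coef"])), p=float(s["p"]),
        ci95=(float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"]))),
        n=len(survival), converged=True, se=float(s["se(coef)"]),
    )


@dataclass(frozen=True)
class MultiCoxFit:
    summary: pd.DataFrame  # index = covariate, columns beta/hr/p/se
    n: int
    converged: bool


def cox_adjusted(values, covariates: pd.DataFrame, survival: SurvivalData,
                 feature_name: str = "feature") -> MultiCoxFit:
    """Cox fit of a feature adjusted for covariates (e.g. age, mutational load)."""
    survival._check_fit()
    x = np.asarray(values, dtype=float)
    cols = {feature_name: x}
    for c in covariates.columns:
        cols[str(c)] = covariates[c].to_numpy(dtype=float)
    mat = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(np.column_stack([mat, np.ones(len(x))])) <= mat.shape[1]:
        return MultiCoxFit(pd.DataFrame(), len(survival), False)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(_cox_frame(survival, cols), duration_col="T", event_col="E")
    except (ConvergenceError, ValueError):
        return MultiCoxFit(pd.DataFrame(), len(survival), False)
    s = cph.summary
    out = pd.DataFrame({
        "beta": s["coef"], "hr": np.exp(s["coef"]), "se": s["se(coef)"], "p": s["p"],
    })
    return MultiCoxFit(out, len(survival), True)


# ---------------------------------------------------------------------------
# vectorized univariate screening (Efron partial likelihood, Newton)
# ---------------------------------------------------------------------------

def _efron_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                  max_iter: int = 25, tol: float = 1e-9):
    """Newton-Raphson on the univariate Efron partial likelihood, one
    independent problem per column of X. Returns (beta, se, converged)."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t, e, Xs = time[order], event[order].astype(float), X[order]
    Xc = Xs - Xs.mean(axis=0)  # centering leaves beta invariant, aids stability

    uniq, starts = np.unique(t, return_index=True)
    G = uniq.size
    d = np.add.reduceat(e, starts)                       # deaths per time group
    sum_x_d = np.add.reduceat(Xc * e[:, None], starts)   # (G, p)
    dmax = int(d.max()) if G else 0

    beta = np.zeros(p)
    converged = np.zeros(p, dtype=bool)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        eta = np.clip(Xc * beta, -500, 500)
        w = np.exp(eta)
        xw = Xc * w
        x2w = Xc * xw
        gs_w = np.add.reduceat(w, starts, axis=0)
        gs_xw = np.add.reduceat(xw, starts, axis=0)
        gs_x2w = np.add.reduceat(x2w, starts, axis=0)
        S = np.cumsum(gs_w[::-1], axis=0)[::-1]      # risk-set sums (G, p)
        U = np.cumsum(gs_xw[::-1], axis=0)[::-1]
        V = np.cumsum(gs_x2w[::-1], axis=0)[::-1]
        S_D = np.add.reduceat(w * e[:, None], starts, axis=0)
        U_D = np.add.reduceat(xw * e[:, None], starts, axis=0)
        V_D = np.add.reduceat(x2w * e[:, None], starts, axis=0)

        grad = sum_x_d.sum(axis=0)
        hess = np.zeros(p)
        for l in range(dmax):
            active = d > l
            frac = np.where(d > 0, l / np.maximum(d, 1), 0.0)[active, None]
            denom = S[active] - frac * S_D[active]
            num_u = U[active] - frac * U_D[active]
            num_v = V[active] - frac * V_D[active]
            r = num_u / denom
            grad -= r.sum(axis=0)
            hess += (num_v / denom - r * r).sum(axis=0)

        info = hess
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(hess > 0, grad / np.maximum(hess, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + np.where(converged, 0.0, step)
        newly = np.abs(step) < tol
        converged |= newly
        if converged.all():
            break

    ok = converged & (info > 0) & (np.abs(beta) < 50)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(ok, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    return beta, se, ok


def screen_features(feature_matrix: pd.DataFrame, survival: SurvivalData,
                    engine: str = "newton") -> pd.DataFrame:
    """Univariate Cox statistics for every feature column.

    Returns a frame indexed by feature with beta / hr / se / p / ci bounds and
    a ``converged`` flag. Constant or partially missing columns are flagged
    non-convergent. ``engine="lifelines"`` fits each feature with lifelines
    instead of the vectorized Newton solver (slow; used for cross-checks).
    """
    survival._check_fit()
    if feature_matrix.shape[0] != len(survival):
        raise ValueError("feature matrix rows must align with survival data")
    X = feature_matrix.to_numpy(dtype=float)
    usable = np.isfinite(X).all(axis=0) & (np.ptp(X, axis=0) > 0)

    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    ok = np.zeros(X.shape[1], dtype=bool)
    if usable.any():
        if engine == "newton":
            b, s, c = _efron_newton(X[:, usable], survival.time, survival.event)
        elif engine == "lifelines":
            cols = np.flatnonzero(usable)
            b = np.empty(cols.size)
            s = np.empty(cols.size)
            c = np.empty(cols.size, dtype=bool)
            for j, col in enumerate(cols):
                fit = cox_univariate(X[:, col], survival)
                b[j], s[j], c[j] = fit.beta, fit.se, fit.converged
        else:
            raise ValueError("engine must be 'newton' or 'lifelines'")
        beta[usable], se[usable], ok[usable] = b, s, c

    with np.errstate(invalid="ignore"):
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "beta": beta,
            "hr": np.exp(beta),
            "se": se,
            "p": p,
            "ci_low": np.exp(beta - 1.959963984540054 * se),
            "ci_high": np.exp(beta + 1.959963984540054 * se),
            "converged": ok,
        },
        index=feature_matrix.columns,
    )
    out.index.name = "feature"
    return out


def select_valid_features(feature_matrix: pd.DataFrame, survival: SurvivalData,
                          alpha: float = ALPHA_DEFAULT,
                          engine: str = "newton") -> tuple[list[str], pd.DataFrame]:
    """Features with univariate Wald p <= alpha, in vocabulary order.

    Non-convergent fits are excluded. No multiplicity correction is applied
    (single-feature screening rule); the returned table carries every fit so
    callers can apply their own correction.
    """
    table = screen_features(feature_matrix, survival, engine=engine)
    table["valid"] = table["converged"] & (table["p"] <= alpha)
    valid = [f for f in feature_matrix.columns if bool(table.at[f, "valid"])]
    if not valid:
        warnings.warn("no feature passed univariate screening", stacklevel=2)
    return valid, table


def write_screening_report(table: pd.DataFrame, path) -> None:
    cols = ["beta", "hr", "p", "ci_low", "ci_high", "valid"]
    table.loc[:, [c for c in cols if c in table.columns]].to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# correlations, KM, log-rank, group comparison
# ---------------------------------------------------------------------------

def feature_correlation_matrix(feature_matrix: pd.DataFrame,
                               features: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of the given feature columns.

    Zero-variance columns yield NaN rows/columns (undefined correlation);
    the diagonal of defined columns is exactly 1.
    """
    sub = feature_matrix if features is None else feature_matrix.loc[:, list(features)]
    if sub.shape[1] < 2:
        raise ValueError("need at least two features")
    corr = sub.corr(method="pearson")
    defined = sub.std(ddof=0) > 0
    np.fill_diagonal(corr.values, np.where(defined, 1.0, np.nan))
    return corr


def km_estimate(survival: SurvivalData) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate: time / survival / n_at_risk."""
    if len(survival) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, survival.event)
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    df = pd.DataFrame({
        "time": et.index.to_numpy(dtype=float),
        "survival": surv.loc[et.index].to_numpy(),
        "n_at_risk": et["at_risk"].to_numpy(dtype=int),
    })
    return df.reset_index(drop=True)


def write_km_curves(groups: dict[str, SurvivalData], path) -> None:
    frames = []
    for label, surv in groups.items():
        df = km_estimate(surv)
        df["group"] = label
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def logrank_test(group_a: SurvivalData, group_b: SurvivalData) -> LogRankResult:
    """Two-group log-rank test (1 df chi-square)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(group_a.time, group_b.time, group_a.event, group_b.event)
    p = max(float(res.p_value), np.finfo(float).tiny)  # floor at machine precision
    return LogRankResult(chi2=float(res.test_statistic), p=p)


def mean_split_stratify(values, survival: SurvivalData):
    """Split at the mean: high = value > mean, low = value <= mean.

    Returns (high_mask, low_mask, LogRankResult). Ties at the mean go to the
    low group; a degenerate split (all values equal) raises.
    """
    x = np.asarray(values, dtype=float)
    if x.shape != survival.time.shape:
        raise ValueError("values must align with survival data")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    high = x > x.mean()
    low = ~high
    if not high.any() or not low.any():
        raise ValueError("mean split produced an empty group (all values equal?)")
    res = logrank_test(survival.subset(high), survival.subset(low))
    return high, low, res


def group_compare(values_a, values_b, equal_var: bool = True):
    """Unpaired two-sample t-test; returns (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
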