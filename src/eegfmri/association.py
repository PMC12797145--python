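"""Inter-participant EEG-fMRI association modelling.

Every (fMRI metric Y, EEG metric X) pair is fitted with the linear
mixed-effects model ``Y ~ 1 + X + Sex + X:Sex`` with a random intercept per
participant (optionally per participant *and* per network), after z-scoring
and 1.5-IQR outlier removal.  Significance is controlled with
Benjamini-Hochberg FDR separately within the pre- and post-correction
families, and the paired pre/post adjusted-r-squared distributions are
compared with a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

from .eeg_metrics import EEG_METRICS
from .fmri_metrics import FMRI_METRICS

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_X_METRICS",
    "DEFAULT_Y_METRICS",
    "AssociationResult",
    "build_grid",
    "zscore_columns",
    "remove_outliers_iqr",
    "fit_lme",
    "fit_pair",
    "fdr_correct",
    "compare_r2",
    "association_grid",
    "polarity_matrix",
]

DEFAULT_Y_METRICS = FMRI_METRICS          # 5 fMRI metrics
DEFAULT_X_METRICS = EEG_METRICS           # 13 EEG metrics (5+1 coherence, 5 power, total, CI)


@dataclass
class AssociationResult:
    """Fixed-effect sizes (standardized coefficients), p-values, adjusted
    r-squared and bookkeeping for one (Y, X, state) fit."""
    y: str
    x: str
    state: str
    beta_x: float
    p_x: float
    beta_sex: float
    p_sex: float
    beta_interaction: float
    p_interaction: float
    ci_x_low: float
    ci_x_high: float
    adj_r2: float
    n_used: int
    n_input: int
    model: str            # "mixedlm", "mixedlm+network", or "ols" fallback
    converged: bool

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def build_grid(fmri_table: pd.DataFrame, eeg_table: pd.DataFrame,
               sex_labels: pd.DataFrame,
               y_metrics: tuple = DEFAULT_Y_METRICS,
               x_metrics: tuple = DEFAULT_X_METRICS) -> dict:
    """Merge the two metric tables into one observation table per
    (Y, X, state) triple, keyed on (participant, network).

    Returns ``{(y, x, state): DataFrame[participant, network, y, x, sex]}``.
    Missing (participant, network) keys on either side shrink the merged
    table (logged); a participant absent from ``sex_labels`` raises.
    """
    out = {}
    eeg_w = eeg_table.pivot_table(index=["participant", "network"],
                                  columns="metric", values="value").reset_index()
    for state in sorted(fmri_table["state"].unique()):
        f = fmri_table[fmri_table["state"] == state]
        fmri_w = f.pivot_table(index=["participant", "network"],
                               columns="metric", values="value").reset_index()
        merged = fmri_w.merge(eeg_w, on=["participant", "network"], how="inner")
        extra = set(merged["participant"]) - set(sex_labels["participant"])
        if extra:
            raise ValueError(f"participants without sex labels: {sorted(extra)}")
        merged = merged.merge(sex_labels, on="participant")
        n_full = fmri_w.shape[0]
        if merged.shape[0] < n_full:
            log.info("state %s: %d of %d keys survive the join", state,
                     merged.shape[0], n_full)
        for y in y_metrics:
            for x in x_metrics:
                if y not in merged.columns or x not in merged.columns:
                    continue
                tab = merged[["participant", "network", y, x, "sex"]].rename(
                    columns={y: "y", x: "x"}).dropna(subset=["y", "x"])
                out[(y, x, state)] = tab.reset_index(drop=True)
    return out


def zscore_columns(table: pd.DataFrame, cols=("y", "x", "sex")) -> pd.DataFrame:
    """Standardize columns to mean 0 / sample SD 1 (ddof = 1).

    A zero-variance column raises ValueError so the caller can skip the pair
    with a reason.
    """
    out = table.copy()
    for c in cols:
        v = out[c].to_numpy(dtype=float)
        sd = np.std(v, ddof=1)
        if sd == 0:
            raise ValueError(f"column '{c}' has zero variance; pair skipped")
        out[c] = (v - v.mean()) / sd
    return out


def remove_outliers_iqr(table: pd.DataFrame, cols=("y", "x"),
                        k: float = 1.5) -> pd.DataFrame:
    """Drop rows where any of ``cols`` falls outside
    [Q1 - k*IQR, Q3 + k*IQR]; quartiles use linear (type-7) interpolation.

    Removing more than half the rows is flagged with a warning.
    """
    if len(table) < 8:
        raise ValueError("need at least 8 rows for IQR fencing")
    keep = np.ones(len(table), dtype=bool)
    for c in cols:
        v = table[c].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75])  # linear interpolation (type 7)
        iqr = q3 - q1
        keep &= (v >= q1 - k * iqr) & (v <= q3 + k * iqr)
    removed = int((~keep).sum())
    if removed:
        log.info("IQR fence removed %d of %d rows", removed, len(table))
    if removed > len(table) / 2:
        warnings.warn(f"IQR fence removed {removed}/{len(table)} rows", stacklevel=2)
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _adjusted_r2(y: np.ndarray, fitted: np.ndarray, n_predictors: int = 3) -> float:
    """1 - (1 - R2_marginal) (n-1)/(n-p-1), with R2_marginal the squared
    correlation between observed Y and the fixed-effects fitted values."""
    n = y.shape[0]
    if n <= n_predictors + 1 or np.std(fitted) == 0 or np.std(y) == 0:
        return np.nan
    r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def fit_lme(table: pd.DataFrame, y: str = "y", x: str = "x", state: str = "pre",
            random_network: bool = False) -> AssociationResult:
    """Fit ``y ~ 1 + x + sex + x:sex`` with a participant random intercept
    (plus a crossed network random intercept when ``random_network``).

    The table is fitted as given — standardize first (see :func:`fit_pair`)
    if standardized effect sizes are wanted.  Singular or non-converging
    mixed fits fall back to OLS, flagged in ``model``/``converged``.
    """
    if table["participant"].nunique() < 2 or table["network"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 networks")
    df = table.copy()
    formula = "y ~ x + sex + x:sex"
    tag = "mixedlm+network" if random_network else "mixedlm"
    res, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if random_network:
                df["_one"] = 1
                md = MixedLM.from_formula(
                    formula, groups="_one",
                    vc_formula={"participant": "0 + C(participant)",
                                "network": "0 + C(network)"},
                    data=df)
            else:
                md = MixedLM.from_formula(formula, groups=df["participant"], data=df)
            res = md.fit(reml=True, method="lbfgs")
            converged = bool(res.converged)
            if converged and not np.all(np.isfinite(
                    res.pvalues[["x", "sex", "x:sex"]])):
                converged = False  # singular information matrix
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is None or not converged:
            res = smf.ols(formula, data=df).fit()
            tag, converged = "ols", True

    params = res.params
    pvals = res.pvalues
    ci = res.conf_int()
    yv = df["y"].to_numpy(dtype=float)
    if tag == "ols":
        fitted = np.asarray(res.fittedvalues)
    else:
        fitted = np.asarray(res.model.exog @ res.fe_params)
    inter = "x:sex"
    return AssociationResult(
        y=y, x=x, state=state,
        beta_x=float(params["x"]), p_x=float(pvals["x"]),
        beta_sex=float(params["sex"]), p_sex=float(pvals["sex"]),
        beta_interaction=float(params[inter]), p_interaction=float(pvals[inter]),
        ci_x_low=float(ci.loc["x", 0]), ci_x_high=float(ci.loc["x", 1]),
        adj_r2=_adjusted_r2(yv, fitted), n_used=len(df), n_input=len(table),
        model=tag, converged=converged)


def fit_pair(table: pd.DataFrame, y: str = "y", x: str = "x", state: str = "pre",
             random_network: bool = False, iqr_k: float = 1.5) -> AssociationResult:
    """Full per-pair pipeline: z-score, 1.5-IQR outlier removal on the
    z-scored values, re-standardize, fit."""
    n_input = len(table)
    z = zscore_columns(table)
    z = remove_outliers_iqr(z, k=iqr_k)
    z = zscore_columns(z)
    res = fit_lme(z, y=y, x=x, state=state, random_network=random_network)
    res.n_input = n_input
    return res


# ---------------------------------------------------------------------------
# inference across the grid
# ---------------------------------------------------------------------------

def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags at level q (one family)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags = np.zeros(p.size, dtype=bool)
    ok = np.isfinite(p)  # undefined p-values are never significant
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


def compare_r2(pre_r2: np.ndarray, post_r2: np.ndarray):
    """Two-sided Wilcoxon signed-rank on post - pre (paired by (Y, X)).

    Zeros are handled by Pratt's method; the exact null is used for n <= 25
    (falling back to the normal approximation with continuity correction when
    zeros make the exact null unavailable).  All-zero differences return
    (0.0, 1.0, flagged).
    """
    pre = np.asarray(pre_r2, dtype=float)
    post = np.asarray(post_r2, dtype=float)
    if pre.shape != post.shape or pre.size < 6:
        raise ValueError("need paired vectors of equal length >= 6")
    d = post - pre
    if np.all(d == 0):
        log.warning("all paired r2 differences are zero")
        return 0.0, 1.0, True
    method = "exact" if (pre.size <= 25 and not np.any(d == 0)) else "approx"
    res = stats.wilcoxon(d, zero_method="pratt", method=method, correction=True)
    return float(res.statistic), float(res.pvalue), False


def association_grid(fmri_table: pd.DataFrame, eeg_table: pd.DataFrame,
                     sex_labels: pd.DataFrame, q: float = 0.05,
                     y_metrics: tuple = DEFAULT_Y_METRICS,
                     x_metrics: tuple = DEFAULT_X_METRICS,
                     random_network: bool = False) -> pd.DataFrame:
    """Fit every (Y, X) pair in every correction state and FDR-correct the
    X-effect, Sex and interaction p-values within each state's family."""
    grid = build_grid(fmri_table, eeg_table, sex_labels, y_metrics, x_metrics)
    rows = []
    for (y, x, state), tab in grid.items():
        try:
            res = fit_pair(tab, y=y, x=x, state=state, random_network=random_network)
        except ValueError as err:
            log.warning("pair (%s, %s, %s) skipped: %s", y, x, state, err)
            continue
        rows.append(res.to_dict())
    out = pd.DataFrame(rows)
    for col in ("x", "sex", "interaction"):
        out[f"sig_{col}"] = False
    for state in out["state"].unique():
        fam = out["state"] == state
        for col in ("x", "sex", "interaction"):
            out.loc[fam, f"sig_{col}"] = fdr_correct(out.loc[fam, f"p_{col}"], q)
    return out


def polarity_matrix(results: pd.DataFrame, state: str = "post",
                    effect: str = "x") -> pd.DataFrame:
    """Signed-significant-effect matrix (rows = fMRI metrics, columns = EEG
    metrics): +1 / -1 for FDR-significant positive / negative effects, 0
    otherwise."""
    sub = results[results["state"] == state]
    signed = np.sign(sub[f"beta_{effect}"]) * sub[f"sig_{effect}"].astype(int)
    mat = sub.assign(polarity=signed.astype(int)).pivot_table(
        index="y", columns="x", values="polarity", aggfunc="first", fill_value=0)
    return mat
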