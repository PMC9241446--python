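"""Longitudinal biomarker statistics.

Per-timepoint correlations with strength bands, standardized partial multiple
regression of the clinical score on the MRI parameters, and the input-output
prediction model whose regression effect size (r^2) is read as predictive
power. A thin group-difference utility wraps the Mann-Whitney test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, StatisticsError
from .synthetic.cohort import CLINICAL_SCORE_LEVELS, COHORT_COLUMNS

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "PredictionResult",
    "correlate",
    "standardized_regression",
    "predictive_power",
    "classify_strength",
    "group_difference",
    "holm_adjust",
    "regression_table",
    "cross_timepoint_table",
    "validate_cohort_table",
    "MRI_PARAMETERS",
]

MRI_PARAMETERS = ("gd_leakage", "pct_fa", "pct_ad", "pct_rd")

_BAND_EDGES = (0.2, 0.4, 0.7)
_BANDS = {
    "correlation": (
        "very weak to negligible correlation",
        "weak correlation",
        "moderate correlation",
        "strong correlation",
    ),
    "effect_size": (
        "none or very weak effect size",
        "weak effect size",
        "moderate effect size",
        "strong effect size",
    ),
}

#: Largest n for which the exact Spearman permutation p-value is enumerated.
_EXACT_PERM_MAX_N = 9


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    band: str


@dataclass
class RegressionResult:
    beta: dict[str, float]
    p: dict[str, float]
    r_squared: float
    band: str
    n: int


@dataclass
class PredictionResult:
    input_name: str
    output_name: str
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int
    band: str


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema check: required columns, one row per animal x dpi, scores on-scale."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise StatisticsError(f"cohort table is missing columns: {missing}")
    if table.duplicated(subset=["animal_id", "dpi"]).any():
        raise StatisticsError("cohort table must have one row per animal x dpi")
    scores = table["clinical_score"].dropna()
    bad = set(scores.unique()) - set(CLINICAL_SCORE_LEVELS)
    if bad:
        raise StatisticsError(f"clinical scores outside the 0-5 scale: {sorted(bad)}")
    return table


def classify_strength(value: float, scale: str = "correlation") -> str:
    """Band label for |r| or r^2; boundary values belong to the upper band."""
    if scale not in _BANDS:
        raise StatisticsError(f"scale must be one of {sorted(_BANDS)}, got {scale!r}")
    v = abs(float(value))
    if v > 1.0 + 1e-12:
        raise StatisticsError(f"|value| must be <= 1, got {value}")
    return _BANDS[scale][int(np.searchsorted(_BAND_EDGES, min(v, 1.0), side="right"))]


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p: enumerate all pairings of y against x.

    Rank correlation is computed as Pearson on (tie-averaged) ranks, which
    reduces to the classical rank-difference formula when ties are absent.
    """
    n = x.size
    if n > _EXACT_PERM_MAX_N:
        raise StatisticsError(
            f"exact permutation p supported for n <= {_EXACT_PERM_MAX_N}, got {n}"
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = np.array(list(itertools.permutations(range(n))))
    r_all = (ry[perms] * rx).mean(axis=1)
    return float((np.abs(r_all) >= abs(r_obs) - 1e-12).mean())


def correlate(
    table: pd.DataFrame,
    x: str,
    y: str,
    dpi: int | None = None,
    method: str = "spearman",
    p_method: str = "approx",
    group: str | None = None,
) -> CorrelationResult:
    """Pairwise-complete correlation of two cohort variables at one timepoint.

    Spearman (default; average ranks for ties, two-sided t-approximate p, or
    an exact permutation p for small n) or Pearson for parameter-parameter
    pairs.
    """
    sub = table
    if dpi is not None:
        sub = sub[sub["dpi"] == dpi]
    if group is not None:
        sub = sub[sub["group"] == group]
    pairs = sub[[x, y]].dropna()
    n = len(pairs)
    if n < 3:
        raise StatisticsError(f"need >= 3 complete pairs, got {n}")
    xv = pairs[x].to_numpy(dtype=float)
    yv = pairs[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise StatisticsError("correlation undefined: a variable has zero variance")

    if method == "spearman":
        r, p = sps.spearmanr(xv, yv)
        if p_method == "exact":
            p = _spearman_exact_p(xv, yv, r)
    elif method == "pearson":
        r, p = sps.pearsonr(xv, yv)
    else:
        raise StatisticsError(f"method must be 'spearman' or 'pearson', got {method!r}")
    r = float(r)
    return CorrelationResult(r=r, p=float(p), n=n, method=method, band=classify_strength(r))


def standardized_regression(
    table: pd.DataFrame,
    response: str = "clinical_score",
    predictors: tuple[str, ...] = MRI_PARAMETERS,
    dpi: int | None = None,
    group: str | None = None,
    cond_limit: float = 1e6,
) -> RegressionResult:
    """Standardized partial regression coefficients (beta) via z-scored OLS.

    All variables are z-scored with the sample mean/SD before an ordinary
    least-squares fit; with a single predictor beta equals the Pearson r.
    Near-perfect collinearity raises an error naming the offending predictors.
    """
    sub = table
    if dpi is not None:
        sub = sub[sub["dpi"] == dpi]
    if group is not None:
        sub = sub[sub["group"] == group]
    cols = [response, *predictors]
    data = sub[cols].dropna()
    n = len(data)
    if n <= len(predictors) + 1:
        raise StatisticsError(f"need n > {len(predictors) + 1} complete cases, got {n}")
    z = (data - data.mean()) / data.std(ddof=1)
    if z.isna().any().any():
        const = [c for c in cols if data[c].std(ddof=1) == 0]
        raise StatisticsError(f"zero-variance variable(s): {const}")

    x = z[list(predictors)].to_numpy()
    cond = float(np.linalg.cond(x))
    if cond > cond_limit:
        corr = np.corrcoef(x, rowvar=False)
        offenders = sorted(
            {
                name
                for i, j in itertools.combinations(range(len(predictors)), 2)
                if abs(corr[i, j]) > 0.999
                for name in (predictors[i], predictors[j])
            }
        ) or list(predictors)
        raise CollinearityError(offenders, cond)

    model = sm.OLS(z[response].to_numpy(), sm.add_constant(x)).fit()
    beta = dict(zip(predictors, (float(b) for b in model.params[1:])))
    pvals = dict(zip(predictors, (float(p) for p in model.pvalues[1:])))
    r2 = float(model.rsquared)
    return RegressionResult(
        beta=beta, p=pvals, r_squared=r2, band=classify_strength(r2, "effect_size"), n=n
    )


def predictive_power(
    table: pd.DataFrame,
    input_dpi: int,
    output_dpi: int | None = None,
    input_var: str = "gd_leakage",
    output_var: str = "pct_rd",
    group: str | None = None,
) -> PredictionResult:
    """Input-output prediction model: simple linear regression across 7 days.

    Regresses ``output_var`` at ``output_dpi`` (default input_dpi + 7) on
    ``input_var`` at ``input_dpi``, pairing within animal; the effect size
    r^2 is reported as predictive power.
    """
    if output_dpi is None:
        output_dpi = input_dpi + 7
    sub = table if group is None else table[table["group"] == group]
    xin = sub[sub["dpi"] == input_dpi].set_index("animal_id")[input_var]
    yout = sub[sub["dpi"] == output_dpi].set_index("animal_id")[output_var]
    pairs = pd.concat([xin, yout], axis=1, join="inner", keys=["x", "y"]).dropna()
    n = len(pairs)
    if n < 3:
        raise StatisticsError(f"need >= 3 paired animals, got {n}")
    fit = sps.linregress(pairs["x"].to_numpy(), pairs["y"].to_numpy())
    r2 = float(fit.rvalue**2)
    return PredictionResult(
        input_name=f"{input_var}@{input_dpi}dpi",
        output_name=f"{output_var}@{output_dpi}dpi",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        p=float(fit.pvalue),
        n=n,
        band=classify_strength(r2, "effect_size"),
    )


def group_difference(
    table: pd.DataFrame,
    variable: str,
    groups: tuple[str, str],
    dpi: int | None = None,
) -> dict[str, float]:
    """Thin reporting utility: two-sided Mann-Whitney U between two groups."""
    sub = table if dpi is None else table[table["dpi"] == dpi]
    a = sub[sub["group"] == groups[0]][variable].dropna().to_numpy()
    b = sub[sub["group"] == groups[1]][variable].dropna().to_numpy()
    if len(a) < 1 or len(b) < 1:
        raise StatisticsError("both groups need at least one observation")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"u": float(u), "p": float(p), "n1": len(a), "n2": len(b)}


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def regression_table(
    table: pd.DataFrame,
    dpis: tuple[int, ...] = (7, 14, 21),
    predictors: tuple[str, ...] = MRI_PARAMETERS,
) -> pd.DataFrame:
    """Per-timepoint grid of standardized beta (p) for the clinical score."""
    rows = {}
    for dpi in dpis:
        res = standardized_regression(table, predictors=predictors, dpi=dpi)
        rows[dpi] = {v: f"{res.beta[v]:.3f} ({res.p[v]:.3g})" for v in predictors}
    out = pd.DataFrame(rows)
    out.index.name = "variable"
    return out


def cross_timepoint_table(
    table: pd.DataFrame,
    input_vars: tuple[str, ...] = ("gd_leakage", "clinical_score"),
    input_dpis: tuple[int, ...] = (7, 14),
    output_vars: tuple[str, ...] = ("pct_fa", "pct_ad", "pct_rd", "clinical_score"),
    output_dpis: tuple[int, ...] = (14, 21),
    group: str | None = None,
) -> pd.DataFrame:
    """Cross-timepoint r (p) grid; Spearman whenever the clinical score is involved."""
    sub = table if group is None else table[table["group"] == group]
    wide = sub.pivot(index="animal_id", columns="dpi")
    rows = []
    for out_dpi in output_dpis:
        for out_var in output_vars:
            row: dict[str, object] = {"dpi": out_dpi, "variable": out_var}
            for in_var in input_vars:
                for in_dpi in input_dpis:
                    if in_dpi >= out_dpi:
                        row[f"{in_var}@{in_dpi}"] = ""
                        continue
                    pair = pd.concat(
                        [wide[(in_var, in_dpi)], wide[(out_var, out_dpi)]], axis=1
                    ).dropna()
                    if len(pair) < 3:
                        row[f"{in_var}@{in_dpi}"] = ""
                        continue
                    method = (
                        "spearman"
                        if "clinical_score" in (in_var, out_var)
                        else "pearson"
                    )
                    if method == "spearman":
                        r, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
                    else:
                        r, p = sps.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                    row[f"{in_var}@{in_dpi}"] = f"{r:.3f} ({p:.3g})"
            rows.append(row)
    return pd.DataFrame(rows)
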