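"""Group summaries, linear models with likelihood-ratio backward
elimination, and correlation/two-group tests.

Linear models are ordinary least squares with a Gaussian error and
identity link, categorical predictors treatment-coded with the DF
breeding site as the reference level.  Model reduction follows
backward elimination: at each step the removable term whose
likelihood-ratio test against the full model has the largest p-value
above ``alpha`` is dropped, interactions always before their main
effects.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

#: treatment-coding reference level per categorical column
_REFERENCES = {"site": "DF", "group": "austral", "sex": "F"}


@dataclass
class LinearModelFit:
    """An OLS fit: per-term estimates, inference, and log-likelihood."""

    response: str
    terms: List[str]              # model terms as supplied
    param_names: List[str]
    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    df_model: int
    loglik: float
    n: int

    def __post_init__(self):
        k = len(self.param_names)
        if not (len(self.estimates) == len(self.se) == len(self.t) == len(self.p) == k):
            raise ValueError("inconsistent parameter vectors")
        if self.df_resid != self.n - k:
            raise ValueError("df_resid must equal n - number of parameters")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.param_names,
                "estimate": self.estimates,
                "se": self.se,
                "t": self.t,
                "p": self.p,
            }
        )

    def __getitem__(self, name: str) -> float:
        """Estimate for a parameter by (partial) name match."""
        for pn, est in zip(self.param_names, self.estimates):
            if name == pn or name in pn:
                return float(est)
        raise KeyError(name)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with its t test."""

    r: float
    t: float
    df: int
    p: float

    def __post_init__(self):
        if abs(self.r) > 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _formula_term(term: str, data: pd.DataFrame) -> str:
    """Wrap categorical columns in treatment coding with fixed reference."""
    parts = term.split(":")
    coded = []
    for part in parts:
        part = part.strip()
        if part in data.columns and (
            data[part].dtype == object or isinstance(data[part].dtype, pd.CategoricalDtype)
        ):
            ref = _REFERENCES.get(part, sorted(data[part].dropna().unique())[0])
            coded.append(f"C({part}, Treatment('{ref}'))")
        else:
            coded.append(part)
    return ":".join(coded)


def _clean_param(name: str) -> str:
    """Collapse the treatment-coding boilerplate in parameter names."""
    return (
        name.replace("C(site, Treatment('DF'))", "site")
        .replace("C(group, Treatment('austral'))", "group")
        .replace("C(sex, Treatment('F'))", "sex")
    )


def fit_lm(response: str, terms: Sequence[str], data: pd.DataFrame) -> LinearModelFit:
    """Ordinary least squares of ``response`` on ``terms``.

    Rows with missing values in any used column are dropped; the design
    must be full rank.  Categorical predictors are treatment-coded with
    the DF site (or first level) as reference.
    """
    terms = list(terms)
    rhs = " + ".join(_formula_term(t, data) for t in terms) if terms else "1"
    model = smf.ols(f"{response} ~ {rhs}", data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = model.fit()
    fit = LinearModelFit(
        response=response,
        terms=terms,
        param_names=[_clean_param(n) for n in res.params.index],
        estimates=res.params.to_numpy(),
        se=res.bse.to_numpy(),
        t=res.tvalues.to_numpy(),
        p=res.pvalues.to_numpy(),
        df_resid=int(res.df_resid),
        df_model=int(res.df_model),
        loglik=float(res.llf),
        n=int(res.nobs),
    )
    return fit


def lrt(full: LinearModelFit, reduced: LinearModelFit) -> Tuple[float, int, float]:
    """Likelihood-ratio test of a nested reduction: (chi2, df, p)."""
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    df = (full.n - full.df_resid) - (reduced.n - reduced.df_resid)
    if df <= 0:
        raise ValueError("reduced model is not nested within full")
    return chi2, df, float(sps.chi2.sf(max(chi2, 0.0), df))


def _removable(terms: Sequence[str]) -> List[str]:
    """Terms not protected by a higher-order interaction still in the model."""
    protected = set()
    for t in terms:
        if ":" in t:
            protected.update(p.strip() for p in t.split(":"))
    return [t for t in terms if t not in protected]


@dataclass
class EliminationStep:
    dropped: str
    chi2: float
    df: int
    p: float


def backward_eliminate(
    response: str,
    terms: Sequence[str],
    data: pd.DataFrame,
    alpha: float = 0.05,
) -> Tuple[LinearModelFit, List[EliminationStep]]:
    """Backward elimination by likelihood-ratio tests.

    Repeatedly drops the removable term with the largest LRT p-value
    above ``alpha`` (interactions are removed before the main effects
    they involve); stops when every remaining removable term is
    significant.  Returns the final fit and the elimination trace.
    """
    current = list(terms)
    trace: List[EliminationStep] = []
    # drop rows missing in any column the *full* model uses, so nested
    # fits share one dataset and the LRTs are valid
    cols = {response}
    for t in terms:
        cols.update(p.strip() for p in t.split(":"))
    data = data.dropna(subset=[c for c in cols if c in data.columns])

    fit = fit_lm(response, current, data)
    while current:
        best: Optional[Tuple[float, str, LinearModelFit, float, int]] = None
        for term in _removable(current):
            reduced = fit_lm(response, [t for t in current if t != term], data)
            chi2, df, p = lrt(fit, reduced)
            if best is None or p > best[0]:
                best = (p, term, reduced, chi2, df)
        if best is None or best[0] <= alpha:
            break
        p, term, reduced, chi2, df = best
        trace.append(EliminationStep(term, chi2, df, p))
        current.remove(term)
        fit = reduced
    return fit, trace


def pearson_test(x, y) -> CorrelationResult:
    """Pearson correlation with the exact t test (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(max(1e-300, 1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(r, float(t), df, p)


def compare_groups(values_a, values_b) -> Tuple[float, float]:
    """Welch two-sample t test (two-sided): returns (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 finite observations")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("degenerate groups (zero variance)")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def group_summary(
    data: pd.DataFrame, group_by: str, variables: Sequence[str]
) -> pd.DataFrame:
    """Per-group mean and sample SD (n-1) of the given variables.

    Missing values are dropped per variable.  Date-valued columns are
    summarised on day-of-year (Jan 1 = 1) and additionally rendered as
    a ``d-Mon`` calendar date.
    """
    rows = []
    for group, sub in data.groupby(group_by):
        if sub.empty:
            raise ValueError(f"empty group {group!r}")
        for var in variables:
            col = sub[var]
            is_date = col.map(lambda v: isinstance(v, (dt.date, pd.Timestamp))).any()
            if is_date:
                vals = pd.to_datetime(pd.Series(list(col))).dt.dayofyear.astype(float)
            else:
                vals = pd.to_numeric(col, errors="coerce")
            vals = vals.dropna()
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            row = dict(group=group, variable=var, n=int(len(vals)), mean=mean, sd=sd)
            if is_date and np.isfinite(mean):
                ref = dt.date(2015, 1, 1) + dt.timedelta(days=round(mean) - 1)
                row["mean_date"] = f"{ref.day}-{ref:%b}"
            rows.append(row)
    return pd.DataFrame(rows)
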