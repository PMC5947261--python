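"""Mixed-model and linear-model inference for niche and body-condition analyses.

The analyses this module serves share one pattern: a Gaussian response, a
small set of fixed effects of which group size (a proxy for intragroup
foraging competition) is the term of interest, and random intercepts for
repeated measures.  Fixed-effect point estimates and standard errors come
from the restricted-likelihood (REML) fit; the significance of each term
comes from a likelihood-ratio test comparing full-likelihood (ML) fits of
the full model against the model with that single term deleted.  Ordinary
linear models use F-tests built from the same full-vs-reduced comparison.
No stepwise reduction is performed: every model is reported in full.

Variance explained is summarised with the marginal / conditional r² for
mixed models: with var_f the variance of the fixed-effect predictor,
var_r the summed random-intercept variances and var_e the residual
variance,

    r²_marginal    = var_f / (var_f + var_r + var_e)
    r²_conditional = (var_f + var_r) / (var_f + var_r + var_e).
"""

from __future__ import annotations

import datetime
import itertools
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .data import GroupCensus, WeightObservation

__all__ = [
    "ModelResult",
    "MissingDataError",
    "daily_weight_change",
    "mean_daily_group_size",
    "classify_group_size",
    "proportion_sampled",
    "fit_lmm",
    "fit_linear_model",
    "likelihood_ratio_test",
    "conditional_r2",
    "spearman_rho",
]

GROUP_SIZE_THRESHOLD = 17
CENSUS_FORWARD_FILL_DAYS = 3
_LRT_TOL = 1e-6


class MissingDataError(ValueError):
    """Required records are absent for the requested computation."""


@dataclass
class ModelResult:
    """Tidy summary of one fitted model."""

    response_name: str
    transform: str  # "identity" or "sqrt"
    coefficients: list[tuple[str, float, float]]  # (term, estimate, se)
    tests: list[tuple[str, float, int, float, str]]  # (term, stat, df, p, kind)
    log_likelihood_full: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    flagged: bool = False
    notes: list[str] = field(default_factory=list)

    def coefficient(self, term: str) -> tuple[float, float]:
        """(estimate, se) for a fixed-effect term, matched by substring."""
        for name, est, se in self.coefficients:
            if name == term or term in name:
                return est, se
        raise KeyError(f"no coefficient matching {term!r}")

    def test(self, term: str) -> tuple[float, int, float, str]:
        for name, stat, df, p, kind in self.tests:
            if name == term or term in name:
                return stat, df, p, kind
        raise KeyError(f"no test matching {term!r}")

    def to_frame(self) -> pd.DataFrame:
        test_map = {t[0]: t[1:] for t in self.tests}
        rows = []
        for name, est, se in self.coefficients:
            stat, df, p, kind = test_map.get(name, (np.nan, 0, np.nan, ""))
            rows.append(
                {
                    "response": self.response_name,
                    "term": name,
                    "estimate": est,
                    "se": se,
                    "statistic": stat,
                    "df": df,
                    "p": p,
                    "kind": kind,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "response": self.response_name,
            "transform": self.transform,
            "log_likelihood": self.log_likelihood_full,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "flagged": self.flagged,
            "coefficients": [
                {"term": t, "estimate": e, "se": s} for t, e, s in self.coefficients
            ],
            "tests": [
                {"term": t, "statistic": s, "df": d, "p": p, "kind": k}
                for t, s, d, p, k in self.tests
            ],
        }


def daily_weight_change(obs: WeightObservation) -> float | None:
    """Second-morning minus first-morning weight (g); None when unpaired."""
    if obs.weight_second_g is None:
        return None
    return obs.weight_second_g - obs.weight_first_g


def mean_daily_group_size(
    census: Sequence[GroupCensus],
    group_id: str,
    start: datetime.date,
    end: datetime.date,
) -> float:
    """Mean daily head count of one group over a date window.

    Census visits are not strictly daily; days without a count are
    forward-filled from the most recent census up to
    :data:`CENSUS_FORWARD_FILL_DAYS` days earlier.  Days beyond that fill
    horizon are excluded from the mean; a window with no coverable day at
    all raises :class:`MissingDataError`.
    """
    if end < start:
        raise MissingDataError(f"empty window {start}..{end}")
    recs = sorted(
        (c for c in census if c.group_id == group_id), key=lambda c: c.date
    )
    if not recs:
        raise MissingDataError(f"no census records for group {group_id!r}")
    dates = [c.date for c in recs]
    values: list[int] = []
    day = start
    one = datetime.timedelta(days=1)
    while day <= end:
        # last census on or before `day`
        idx = np.searchsorted([d.toordinal() for d in dates], day.toordinal(), side="right") - 1
        if idx >= 0 and (day - dates[idx]).days <= CENSUS_FORWARD_FILL_DAYS:
            values.append(recs[idx].n_members)
        day += one
    if not values:
        raise MissingDataError(
            f"no census within {CENSUS_FORWARD_FILL_DAYS} days of any day in "
            f"{start}..{end} for group {group_id!r}"
        )
    return float(np.mean(values))


def classify_group_size(mean_size: float, threshold: float = GROUP_SIZE_THRESHOLD) -> str:
    """'small' strictly below the threshold, 'large' at or above it.

    The observed group sizes are bimodal with a gap at the threshold, so no
    datum sits on the boundary; the boundary itself is assigned to 'large'.
    """
    if mean_size <= 0:
        raise ValueError(f"mean group size must be positive, got {mean_size}")
    return "small" if mean_size < threshold else "large"


def proportion_sampled(roster: Sequence[str], holders: Sequence[str]) -> float:
    """Fraction of a group's roster with an estimable niche ellipse."""
    roster_set = set(roster)
    holder_set = set(holders)
    if not roster_set:
        raise ValueError("group roster is empty")
    if not holder_set <= roster_set:
        raise ValueError("holders must be a subset of the roster")
    return len(holder_set) / len(roster_set)


def likelihood_ratio_test(
    loglik_full: float, loglik_reduced: float, df_diff: int
) -> tuple[float, float]:
    """χ² = 2·(ℓ_full − ℓ_reduced) with an upper-tail chi-square p-value."""
    if df_diff < 1:
        raise ValueError(f"df_diff must be >= 1, got {df_diff}")
    chi2 = 2.0 * (loglik_full - loglik_reduced)
    if chi2 < -_LRT_TOL:
        warnings.warn(
            f"reduced model fits better than full (chi2={chi2:.3g}); "
            "likely a convergence failure — consider refitting",
            stacklevel=2,
        )
    chi2 = max(chi2, 0.0)
    return chi2, float(stats.chi2.sf(chi2, df=df_diff))


def conditional_r2(
    var_fixed: float, var_random: float, var_resid: float, marginal: bool = False
) -> float:
    """Variance-partition r² for mixed models (conditional by default)."""
    if min(var_fixed, var_random, var_resid) < 0:
        raise ValueError("variance components must be non-negative")
    total = var_fixed + var_random + var_resid
    if total == 0:
        raise ValueError("all variance components are zero")
    numer = var_fixed if marginal else var_fixed + var_random
    return numer / total


def _formula(response: str, terms: Sequence[str]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _check_modelled_columns(table: pd.DataFrame, columns: Sequence[str]) -> None:
    base = {c for col in columns for c in _columns_in(col)}
    missing = base - set(table.columns)
    if missing:
        raise KeyError(f"model columns not in table: {sorted(missing)}")
    if table[sorted(base)].isna().any().any():
        bad = [c for c in sorted(base) if table[c].isna().any()]
        raise MissingDataError(f"missing values in modelled column(s): {bad}")


_FORMULA_FUNCS = {"C", "Treatment", "I", "Q", "np", "log", "sqrt", "center", "scale"}


def _columns_in(term: str) -> list[str]:
    # column names referenced by a patsy term such as C(sex) or
    # C(size_class, Treatment('small')); quoted literals are not columns
    bare = re.sub(r"'[^']*'|\"[^\"]*\"", "", term)
    names = re.findall(r"[A-Za-z_][A-Za-z0-9_]*", bare)
    return [n for n in names if n not in _FORMULA_FUNCS]


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed_terms: Sequence[str],
    random_groups: Sequence[str],
) -> ModelResult:
    """Gaussian linear mixed model with random intercepts.

    ``random_groups`` names one or two grouping columns.  With two, the
    coarser one (fewer levels) becomes the primary grouping and the finer
    one enters as a variance component, which covers the nested
    individual-within-group designs used here.  Estimates and standard
    errors come from the REML fit; each fixed term's χ² is a full-vs-deleted
    ML likelihood-ratio test.
    """
    fixed_terms = list(fixed_terms)
    random_groups = list(random_groups)
    if not random_groups:
        raise ValueError("fit_lmm requires at least one random grouping")
    _check_modelled_columns(table, [response, *fixed_terms, *random_groups])
    for g in random_groups:
        if table[g].nunique() < 2:
            raise ValueError(f"random grouping {g!r} has fewer than 2 levels")

    groups_col = min(random_groups, key=lambda c: table[c].nunique())
    vc = {c: f"0 + C({c})" for c in random_groups if c != groups_col}

    flagged = False
    notes: list[str] = []

    def _fit(formula: str, reml: bool):
        nonlocal flagged
        model = smf.mixedlm(
            formula,
            table,
            groups=table[groups_col],
            re_formula="1",
            vc_formula=vc or None,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = None
            last_exc: Exception | None = None
            # lbfgs occasionally walks into a singular profiled system on
            # near-boundary variance components; derivative-free methods
            # are slower but robust
            for method in ("lbfgs", "powell", "nm"):
                try:
                    result = model.fit(reml=reml, method=method, maxiter=2000)
                    break
                except np.linalg.LinAlgError as exc:
                    last_exc = exc
                    flagged = True
            if result is None:
                raise last_exc
        for w in caught:
            if "singular" in str(w.message).lower() or "boundary" in str(w.message).lower():
                flagged = True
        return result

    full_formula = _formula(response, fixed_terms)
    reml_fit = _fit(full_formula, reml=True)
    ml_fit = _fit(full_formula, reml=False)

    coefficients = [
        (term, float(reml_fit.fe_params[term]), float(reml_fit.bse_fe[term]))
        for term in reml_fit.fe_params.index
    ]

    tests = []
    for term in fixed_terms:
        reduced = [t for t in fixed_terms if t != term]
        red_fit = _fit(_formula(response, reduced), reml=False)
        df_diff = len(ml_fit.fe_params) - len(red_fit.fe_params)
        chi2, p = likelihood_ratio_test(float(ml_fit.llf), float(red_fit.llf), df_diff)
        tests.append((term, chi2, df_diff, p, "LRT"))

    exog = reml_fit.model.exog
    var_f = float(np.var(exog @ reml_fit.fe_params.values))
    var_r = float(np.trace(np.atleast_2d(reml_fit.cov_re)))
    if reml_fit.vcomp is not None and len(reml_fit.vcomp):
        var_r += float(np.sum(reml_fit.vcomp))
    var_e = float(reml_fit.scale)

    return ModelResult(
        response_name=response,
        transform="identity",
        coefficients=coefficients,
        tests=tests,
        log_likelihood_full=float(ml_fit.llf),
        r2_marginal=conditional_r2(var_f, var_r, var_e, marginal=True),
        r2_conditional=conditional_r2(var_f, var_r, var_e),
        n_obs=int(len(table)),
        n_groups=int(table[groups_col].nunique()),
        flagged=flagged,
        notes=notes,
    )


def fit_linear_model(
    table: pd.DataFrame, response: str, terms: Sequence[str]
) -> ModelResult:
    """Ordinary least squares with per-term full-vs-reduced F-tests."""
    terms = list(terms)
    _check_modelled_columns(table, [response, *terms])
    full = smf.ols(_formula(response, terms), table).fit()
    k = full.model.exog.shape[1]
    n = int(full.nobs)
    if n <= k:
        raise ValueError(f"{n} observations cannot support {k} parameters")

    rss_full = float(full.ssr)
    df_resid = int(full.df_resid)
    flagged = False
    tests = []
    for term in terms:
        reduced = smf.ols(_formula(response, [t for t in terms if t != term]), table).fit()
        df_diff = int(reduced.df_resid - full.df_resid)
        if rss_full <= 1e-12 * max(float(reduced.ssr), 1.0):
            stat, p = math.inf, 0.0
            flagged = True
        else:
            stat = ((float(reduced.ssr) - rss_full) / df_diff) / (rss_full / df_resid)
            stat = max(stat, 0.0)
            p = float(stats.f.sf(stat, df_diff, df_resid))
        tests.append((term, stat, df_diff, p, "F"))

    var_f = float(np.var(full.fittedvalues))
    var_e = float(rss_full / df_resid) if df_resid > 0 else 0.0
    r2 = conditional_r2(var_f, 0.0, var_e) if (var_f + var_e) > 0 else 0.0

    return ModelResult(
        response_name=response,
        transform="identity",
        coefficients=[
            (t, float(full.params[t]), float(full.bse[t])) for t in full.params.index
        ],
        tests=tests,
        log_likelihood_full=float(full.llf),
        r2_marginal=r2,
        r2_conditional=r2,
        n_obs=n,
        n_groups=n,
        flagged=flagged,
    )


def _rank_corr(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(xc @ yc) / denom


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    For n ≤ 10 the p-value is exact, from the full permutation distribution
    of the rank correlation under independence; for larger n the usual
    t-approximation is used.  Two-sided throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = _rank_corr(xr, yr)

    if n <= 10:
        count = 0
        total = 0
        xc = xr - xr.mean()
        y_center = yr - yr.mean()
        denom_y = float(y_center @ y_center)
        denom = math.sqrt(float(xc @ xc) * denom_y)
        target = abs(rho) * denom - 1e-12
        for perm in itertools.permutations(range(n)):
            num = float(xc @ y_center[list(perm)])
            if abs(num) >= target:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)
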