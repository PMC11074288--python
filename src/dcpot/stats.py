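"""Repeated-measures inference: two-way RM ANOVA, Tukey HSD, Bayes-factor
categories and a priori power.

The design treats every factor (session, condition, area, time) as within
subject. Two-way repeated-measures ANOVA uses the classical univariate
partitioning in which each effect is tested against its own
subject-by-effect interaction; no sphericity correction is applied by
default (epsilon is reported descriptively).

Post hoc pairwise comparisons use Tukey's studentized-range procedure with
the within-subject error term of the collapsed one-way design, so for two
levels the Tukey p equals the paired t-test p (q = sqrt(2)|t|).

Bayes factors are approximated from BICs of mixed models with subject
intercepts, logBF10 ~= (BIC_null - BIC_full) / 2 — a light-weight
approximation whose contract is the evidence *category*, banded as
anecdotal [0, 1.1), substantial [1.1, 2.3), strong [2.3, 3.4],
very strong (3.4, 4.6] and decisive (> 4.6).

Power for a within-subjects factor with m measurements follows the
noncentral-F convention lambda = f^2 * n * m * eps / (1 - rho), with
df1 = (m - 1) * eps and df2 = (n - 1) * (m - 1) * eps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "BayesResult",
    "PowerResult",
    "rm_anova_two_way",
    "tukey_hsd",
    "logbf_rm_anova",
    "classify_evidence",
    "power_rm_anova",
    "significance_stars",
    "MissingCellError",
]


class MissingCellError(ValueError):
    """The within-subject design is incomplete or unbalanced."""


#: Significance star bands used throughout figure-style reporting.
_STAR_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in _STAR_BANDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class AnovaResult:
    """F tests of the two main effects and their interaction."""

    factors: tuple[str, str]
    effects: dict[str, dict[str, float]]  # effect -> {F, df1, df2, p}
    n_subjects: int

    def effect(self, name: str) -> dict[str, float]:
        return self.effects[name]

    @property
    def interaction(self) -> dict[str, float]:
        return self.effects[f"{self.factors[0]} * {self.factors[1]}"]


@dataclass
class PosthocResult:
    """All pairwise Tukey contrasts of one factor's levels."""

    factor: str
    table: pd.DataFrame  # level_a, level_b, mean_diff, q, p_tukey, stars

    def contrast(self, a: str, b: str) -> pd.Series:
        t = self.table
        row = t[((t.level_a == a) & (t.level_b == b)) | ((t.level_a == b) & (t.level_b == a))]
        if len(row) == 0:
            raise KeyError(f"no contrast {a!r} vs {b!r}")
        return row.iloc[0]


@dataclass
class BayesResult:
    logbf10: float
    category: str
    flagged: bool = False
    diagnostic: str = ""


@dataclass
class PowerResult:
    f: float
    alpha: float
    rho: float
    eps: float
    m: int
    n: int
    actual_power: float
    target_power: float | None = None


def _check_balanced(
    df: pd.DataFrame, dv: str, factors: tuple[str, str], subject: str
) -> tuple[pd.DataFrame, int]:
    for col in (dv, subject, *factors):
        if col not in df.columns:
            raise MissingCellError(f"table lacks column {col!r}")
    cell = df.groupby([subject, *factors], observed=True)[dv].count()
    subjects = df[subject].unique()
    levels_a = df[factors[0]].unique()
    levels_b = df[factors[1]].unique()
    expected = len(subjects) * len(levels_a) * len(levels_b)
    if (cell != 1).any() or len(cell) != expected:
        counted = cell[cell != 1]
        missing = expected - len(cell)
        raise MissingCellError(
            f"design is not complete/balanced: {missing} missing cells; "
            f"strata with != 1 observation: {list(counted.index[:10])}"
        )
    if len(subjects) < 3:
        raise MissingCellError("repeated-measures ANOVA needs >= 3 subjects")
    return df, len(subjects)


def rm_anova_two_way(
    df: pd.DataFrame,
    dv: str = "value",
    factors: tuple[str, str] = ("session", "condition"),
    subject: str = "subject",
) -> AnovaResult:
    """Two-way fully within-subjects ANOVA on a long-format table.

    Every subject must contribute exactly one observation per factor-level
    combination (raw per-subject metric values, not cohort means). Each
    effect is tested against its subject-by-effect interaction mean square.
    """
    df, n_subj = _check_balanced(df, dv, factors, subject)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(
            data=df, dv=dv, within=list(factors), subject=subject, detailed=True
        )
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    effects: dict[str, dict[str, float]] = {}
    for _, row in aov.iterrows():
        effects[str(row["Source"])] = {
            "F": float(row["F"]),
            "df1": float(row["ddof1"]),
            "df2": float(row["ddof2"]),
            "p": float(row[p_col]),
            # sphericity estimate, reported descriptively (no correction)
            "eps": float(row["eps"]) if "eps" in aov.columns else float("nan"),
        }
    return AnovaResult(factors=factors, effects=effects, n_subjects=n_subj)


def tukey_hsd(
    df: pd.DataFrame,
    dv: str = "value",
    factor: str = "condition",
    subject: str = "subject",
) -> PosthocResult:
    """Tukey studentized-range contrasts between a within factor's levels.

    The table is first collapsed to subject-by-level cell means (averaging
    over any other factors), then the one-way repeated-measures error term
    MS(subject x level) feeds q = |mean_i - mean_j| / sqrt(MS_err / n) with
    k levels and (k - 1)(n - 1) error degrees of freedom.
    """
    levels = list(pd.unique(df[factor]))
    if len(levels) < 2:
        raise MissingCellError(f"factor {factor!r} has <2 levels")
    cellmeans = (
        df.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    )
    if cellmeans.isna().any().any():
        raise MissingCellError(
            f"incomplete design: some subjects lack levels of {factor!r}"
        )
    y = cellmeans[levels].to_numpy()  # (n_subjects, k)
    n, k = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1, keepdims=True)
    level_means = y.mean(axis=0, keepdims=True)
    resid = y - subj_means - level_means + grand
    df_err = (n - 1) * (k - 1)
    ms_err = float((resid**2).sum() / df_err)
    se = np.sqrt(ms_err / n)
    rows = []
    for a, b in combinations(levels, 2):
        diff = float(cellmeans[a].mean() - cellmeans[b].mean())
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        p = min(1.0, max(0.0, p))
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": diff,
                "q": q,
                "p_tukey": p,
                "stars": significance_stars(p),
            }
        )
    return PosthocResult(factor=factor, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def _mixed_bic(df: pd.DataFrame, formula: str, subject: str) -> float:
    import statsmodels.formula.api as smf

    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df[subject])
        # lbfgs can return llf=inf or raise on near-singular RE variance;
        # fall through to sturdier optimizers before giving up.
        for method in ("lbfgs", "powell", "bfgs"):
            try:
                cand = model.fit(reml=False, method=method)
            except np.linalg.LinAlgError:
                continue
            if np.isfinite(cand.llf):
                fit = cand
                break
    if fit is None:
        raise np.linalg.LinAlgError(f"no optimizer produced a finite fit for {formula!r}")
    k = len(fit.params) + 1  # fixed effects + RE variance + residual scale
    n = len(df)
    return float(-2.0 * fit.llf + k * np.log(n))


def logbf_rm_anova(
    df: pd.DataFrame,
    dv: str = "value",
    factors: tuple[str, str] = ("session", "condition"),
    subject: str = "subject",
    include_interaction: bool = True,
) -> BayesResult:
    """BIC-approximated log Bayes factor for the factorial model vs null.

    Both models carry a subject random intercept; the null has no fixed
    effects. logBF10 ~= (BIC_null - BIC_full)/2; the reliable output is the
    evidence category, not the third decimal.
    """
    df, _ = _check_balanced(df, dv, factors, subject)
    data = df.rename(columns={dv: "_dv"}).copy()
    fa, fb = factors
    rhs = f"C({fa}) * C({fb})" if include_interaction else f"C({fa}) + C({fb})"
    flagged, diagnostic = False, ""
    try:
        bic_full = _mixed_bic(data, f"_dv ~ {rhs}", subject)
        bic_null = _mixed_bic(data, "_dv ~ 1", subject)
        logbf = (bic_null - bic_full) / 2.0
    except Exception as exc:  # singular fits surface as np.linalg errors
        flagged, diagnostic = True, f"mixed-model fit failed: {exc}"
        logbf = float("nan")
    category = classify_evidence(logbf) if np.isfinite(logbf) else "undetermined"
    return BayesResult(
        logbf10=logbf, category=category, flagged=flagged, diagnostic=diagnostic
    )


def classify_evidence(logbf10: float) -> str:
    """Evidence category for a natural-log Bayes factor.

    Bands: anecdotal [0, 1.1), substantial [1.1, 2.3), strong [2.3, 3.4],
    very strong (3.4, 4.6], decisive (> 4.6). Negative values mirror the
    magnitude with a "favors null" prefix.
    """
    if not np.isfinite(logbf10):
        raise ValueError(f"logbf10 must be finite, got {logbf10}")
    if logbf10 < 0:
        return f"favors null ({classify_evidence(-logbf10)})"
    if logbf10 < 1.1:
        return "anecdotal"
    if logbf10 < 2.3:
        return "substantial"
    if logbf10 <= 3.4:
        return "strong"
    if logbf10 <= 4.6:
        return "very strong"
    return "decisive"


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def _rm_power(f: float, alpha: float, rho: float, eps: float, m: int, n: int) -> float:
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    if df2 <= 0:
        return 0.0
    lam = f**2 * n * m * eps / (1.0 - rho)
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def power_rm_anova(
    f: float,
    alpha: float = 0.05,
    rho: float = 0.5,
    eps: float = 1.0,
    m: int = 2,
    n: int | None = None,
    target_power: float | None = None,
    max_n: int = 10**6,
) -> PowerResult:
    """Power of the within-subjects F test, or the smallest n achieving it.

    ``f`` is Cohen's effect size (f = 0.3333 corresponds to partial eta
    squared of 0.1); ``rho`` the correlation among repeated measures,
    ``eps`` the nonsphericity correction, ``m`` the number of repeated
    measurements. Provide ``n`` for post hoc power or ``target_power`` for
    the a priori sample size.
    """
    if f <= 0:
        raise ValueError("effect size f must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if not 0 < eps <= 1:
        raise ValueError("eps must lie in (0, 1]")
    if m < 2:
        raise ValueError("need at least m = 2 repeated measurements")
    if (n is None) == (target_power is None):
        raise ValueError("provide exactly one of n or target_power")
    if n is not None:
        return PowerResult(
            f=f, alpha=alpha, rho=rho, eps=eps, m=m, n=n,
            actual_power=_rm_power(f, alpha, rho, eps, m, n),
        )
    for cand in range(2, max_n + 1):
        p = _rm_power(f, alpha, rho, eps, m, cand)
        if p >= target_power:
            return PowerResult(
                f=f, alpha=alpha, rho=rho, eps=eps, m=m, n=cand,
                actual_power=p, target_power=target_power,
            )
    raise ValueError(f"target power {target_power} unattainable within n <= {max_n}")
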