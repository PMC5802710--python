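"""Inferential layer: goodness-of-fit on affected proportions, the
integer-count inversion used for cross-checking published statistics,
and the averaged-group two-way ANOVA with Bonferroni post hoc tests.

The goodness-of-fit statistic is the classical two-category Pearson
chi-squared against fixed reference proportions,

    chi2 = sum_i (O_i - n p_i)^2 / (n p_i),   df = 1,

with no continuity correction. Because the observed counts are integers
and n is small, a printed chi-squared value (2 decimal places) usually
pins down the affected count uniquely; :func:`invert_gof` exploits this
to recover counts from published statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import AnalysisError, ConfigError
from .io import BehaviorTable
from .profiling import GroupDistribution

__all__ = [
    "GofResult",
    "EffectTest",
    "AnovaResult",
    "PairwiseComparison",
    "gof_test",
    "chi2_sf",
    "invert_gof",
    "behavior_design",
    "anova_two_way",
    "bonferroni_posthoc",
]


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GofResult:
    """Two-category chi-squared goodness-of-fit result."""

    chi2: float
    df: int
    p: float
    observed: tuple[int, int]
    expected: tuple[float, float]
    reference: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "observed": list(self.observed),
            "expected": list(self.expected),
            "reference": list(self.reference),
        }


def _observed_pair(observed) -> tuple[int, int]:
    if isinstance(observed, GroupDistribution):
        return observed.n_affected, observed.n_unaffected
    a, b = observed
    a, b = int(a), int(b)
    if a < 0 or b < 0:
        raise AnalysisError("observed counts must be non-negative")
    return a, b


def gof_test(observed, reference: Sequence[float] = (0.20, 0.80)) -> GofResult:
    """Pearson goodness of fit of an (affected, unaffected) split
    against fixed reference proportions.

    ``observed`` is a :class:`GroupDistribution` or an
    ``(n_affected, n_unaffected)`` pair. No continuity correction is
    applied; df = 1 for the two categories.
    """
    n_aff, n_unaff = _observed_pair(observed)
    n = n_aff + n_unaff
    if n < 1:
        raise AnalysisError("goodness-of-fit test needs at least one animal")
    p_aff, p_unaff = float(reference[0]), float(reference[1])
    if not (0 < p_aff < 1 and 0 < p_unaff < 1):
        raise AnalysisError(
            f"reference proportions must lie in (0, 1), got {reference}"
        )
    if abs(p_aff + p_unaff - 1.0) > 1e-9:
        raise AnalysisError(
            f"reference proportions must sum to 1, got {p_aff} + {p_unaff}"
        )
    e_aff, e_unaff = n * p_aff, n * p_unaff
    if e_aff == 0 or e_unaff == 0:
        raise AnalysisError("degenerate reference: an expected count is zero")
    chi2 = (n_aff - e_aff) ** 2 / e_aff + (n_unaff - e_unaff) ** 2 / e_unaff
    return GofResult(
        chi2=float(chi2),
        df=1,
        p=chi2_sf(float(chi2), 1),
        observed=(n_aff, n_unaff),
        expected=(e_aff, e_unaff),
        reference=(p_aff, p_unaff),
    )


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution.

    For df = 1 this reduces to erfc(sqrt(x/2)); general df uses the
    regularised upper incomplete gamma function Q(df/2, x/2).
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if x < 0:
        raise ValueError(f"chi-squared statistic must be >= 0, got {x}")
    if df == 1:
        return float(special.erfc(np.sqrt(x / 2.0)))
    return float(special.gammaincc(df / 2.0, x / 2.0))


def invert_gof(
    chi2_printed: float,
    n: int,
    reference: Sequence[float],
    tol_dp: int = 2,
) -> tuple[int, ...]:
    """Recover the integer affected count(s) behind a printed statistic.

    Exhaustively tests every count x in 0..n and returns those whose
    goodness-of-fit statistic against ``reference`` rounds to
    ``chi2_printed`` at ``tol_dp`` decimal places. An empty tuple means
    the printed value is inconsistent with any integer count.
    """
    if n < 1:
        raise AnalysisError("n must be >= 1")
    target = round(float(chi2_printed), tol_dp)
    hits = [
        x
        for x in range(n + 1)
        if round(gof_test((x, n - x), reference).chi2, tol_dp) == target
    ]
    return tuple(hits)


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectTest:
    """One F test from an ANOVA table."""

    effect: str
    ss: float
    df_num: int
    df_den: int
    F: float
    p: float

    def as_dict(self) -> dict:
        return {
            "effect": self.effect,
            "ss": self.ss,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "F": self.F,
            "p": self.p,
        }


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects two-way ANOVA with interaction."""

    response: str
    factor_a: str
    factor_b: str
    effects: tuple[EffectTest, ...]
    residual_ss: float
    residual_df: int
    ss_type: int

    def effect(self, name: str) -> EffectTest:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    def as_dict(self) -> dict:
        return {
            "response": self.response,
            "factors": [self.factor_a, self.factor_b],
            "ss_type": self.ss_type,
            "effects": [e.as_dict() for e in self.effects],
            "residual": {"ss": self.residual_ss, "df": self.residual_df},
        }


def behavior_design(
    table: BehaviorTable,
    factor_names: Sequence[str],
    group_factors: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Expand a behavior table into an ANOVA design frame.

    Adds one column per design factor, derived from the group label via
    ``group_factors`` (e.g. ``"JVS+FLXjuv" -> ("JVS", "FLXjuv")``).
    """
    df = table.frame
    unmapped = sorted(set(df["group"]) - set(group_factors))
    if unmapped:
        raise ConfigError(
            f"no factor mapping for group(s): {', '.join(unmapped)}"
        )
    for i, name in enumerate(factor_names):
        df[name] = [group_factors[g][i] for g in df["group"]]
    return df


def _check_design(df: pd.DataFrame, factor_a: str, factor_b: str) -> None:
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    levels_a = df[factor_a].unique()
    levels_b = df[factor_b].unique()
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in counts.index:
                raise AnalysisError(
                    f"empty design cell ({factor_a}={a!r}, {factor_b}={b!r})"
                )
    n = len(df)
    cells = len(levels_a) * len(levels_b)
    if n - cells <= 0:
        raise AnalysisError(
            f"no residual degrees of freedom: {n} observations in {cells} cells"
        )


def anova_two_way(
    data: BehaviorTable | pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    ss_type: int = 3,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction.

    By default uses Type III sums of squares with sum-to-zero contrasts,
    the convention that matches mainstream commercial statistics
    packages for unbalanced factorial designs; Types I and II are
    available via ``ss_type``. ``data`` is a design frame containing the
    response and both factor columns (see :func:`behavior_design`), or a
    :class:`BehaviorTable` whose ``group`` column already is one of the
    factors.
    """
    df = data.frame if isinstance(data, BehaviorTable) else data.copy()
    for col in (response, factor_a, factor_b):
        if col not in df.columns:
            raise ConfigError(f"column {col!r} not present in the design frame")
    if ss_type not in (1, 2, 3):
        raise ConfigError("ss_type must be 1, 2 or 3")
    _check_design(df, factor_a, factor_b)

    df = df.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    # a single-level factor contributes no terms: the model collapses to
    # the one-way ANOVA in the other factor
    terms = [t for t, col in (("C(_a, Sum)", "_a"), ("C(_b, Sum)", "_b"))
             if df[col].nunique() > 1]
    formula = "_y ~ " + (" * ".join(terms) if terms else "1")
    model = smf.ols(formula, data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        tab = sm.stats.anova_lm(model, typ=ss_type)

    label = {"C(_a, Sum)": factor_a, "C(_b, Sum)": factor_b,
             "C(_a, Sum):C(_b, Sum)": f"{factor_a}:{factor_b}"}
    resid_ss = float(tab.loc["Residual", "sum_sq"])
    resid_df = int(tab.loc["Residual", "df"])
    scale = float(np.square(df["_y"]).sum()) or 1.0
    effects = []
    for row, name in label.items():
        if row not in tab.index:
            # absent term (single-level factor): zero sum of squares
            effects.append(EffectTest(name, 0.0, 0, resid_df, 0.0, 1.0))
            continue
        ss = float(tab.loc[row, "sum_sq"])
        dfn = int(tab.loc[row, "df"])
        F = float(tab.loc[row, "F"])
        p = float(tab.loc[row, "PR(>F)"])
        # saturated/degenerate fits: define F from the sums of squares
        if ss <= 1e-12 * scale:
            F, p = 0.0, 1.0
        elif not np.isfinite(F):
            F, p = float("inf"), 0.0
        effects.append(EffectTest(name, ss, dfn, resid_df, F, p))
    return AnovaResult(
        response=response,
        factor_a=factor_a,
        factor_b=factor_b,
        effects=tuple(effects),
        residual_ss=resid_ss,
        residual_df=resid_df,
        ss_type=ss_type,
    )


# ---------------------------------------------------------------------------
# Bonferroni post hoc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseComparison:
    """One Bonferroni-adjusted pairwise t comparison."""

    level_a: str
    level_b: str
    mean_a: float
    mean_b: float
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "levels": [self.level_a, self.level_b],
            "means": [self.mean_a, self.mean_b],
            "t": self.t,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
        }


def bonferroni_posthoc(
    data: BehaviorTable | pd.DataFrame,
    response: str,
    factor: str,
    alpha: float = 0.05,
    error_mse: float | None = None,
    error_df: int | None = None,
) -> list[PairwiseComparison]:
    """All pairwise t comparisons of a factor's levels with Bonferroni
    adjustment over that factor only.

    The error term defaults to the pooled within-level variance (the
    one-way residual mean square); pass ``error_mse``/``error_df`` to
    reuse the residual from a surrounding two-way ANOVA instead. The
    adjusted p is min(1, raw p * number of comparisons).
    """
    df = data.frame if isinstance(data, BehaviorTable) else data
    for col in (response, factor):
        if col not in df.columns:
            raise ConfigError(f"column {col!r} not present in the design frame")
    groups = {lvl: sub[response].to_numpy(dtype=float)
              for lvl, sub in df.groupby(factor, observed=True)}
    levels = list(groups)
    if len(levels) < 2:
        raise AnalysisError(
            f"factor {factor!r} needs >= 2 levels for post hoc comparisons"
        )
    if error_mse is None or error_df is None:
        n_total = sum(len(v) for v in groups.values())
        dof = n_total - len(levels)
        if dof <= 0:
            raise AnalysisError("no residual degrees of freedom for the error term")
        ss = sum(float(np.square(v - v.mean()).sum()) for v in groups.values())
        mse, dof = ss / dof, dof
    else:
        mse, dof = float(error_mse), int(error_df)

    m = len(levels) * (len(levels) - 1) // 2
    out = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            va, vb = groups[a], groups[b]
            diff = float(va.mean() - vb.mean())
            se = np.sqrt(mse * (1.0 / len(va) + 1.0 / len(vb)))
            if se == 0.0:
                t = 0.0 if diff == 0.0 else float("inf")
            else:
                t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
            p_adj = min(1.0, p * m)
            out.append(
                PairwiseComparison(
                    level_a=str(a),
                    level_b=str(b),
                    mean_a=float(va.mean()),
                    mean_b=float(vb.mean()),
                    t=float(t),
                    df=dof,
                    p_raw=p,
                    p_adjusted=p_adj,
                    significant=p_adj < alpha,
                )
            )
    return out
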