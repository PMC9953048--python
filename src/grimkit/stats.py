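"""Statistical battery for facial-parameter units and response profiles.

Covers: one-sample response profiles with Bonferroni adjustment, one-way
ANOVA with Tukey HSD, two-way (optionally mixed-design) ANOVA with
Greenhouse–Geisser correction and Tukey/Šidák post hocs, repeated-measures
ANOVA with Dunnett comparisons against baseline, inter-observer ICC(2,1),
Pearson covariate controls, and Welch two-sample tests.

All tests are two-sided at alpha = 0.05 unless configured otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landmark_model import PARAMETER_NAMES

__all__ = [
    "TTestResult",
    "AnovaResult",
    "PosthocResult",
    "ICCResult",
    "CorrelationResult",
    "DegenerateSampleError",
    "response_profile",
    "one_way_anova",
    "two_way_anova",
    "rm_anova_dunnett",
    "dunnett_rm_pvalues",
    "icc",
    "pearson_control",
    "welch_t",
    "sidak_adjust",
]


class DegenerateSampleError(ValueError):
    """Sample has zero variance (or too few observations) for the test."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_raw: float
    p_adj: float
    m: int = 1

    def __post_init__(self):
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adj <= 1.0):
            raise ValueError("p values must lie in [0, 1]")
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    epsilon: Optional[float] = None  # sphericity correction factor, (0, 1]


@dataclass(frozen=True)
class PosthocResult:
    method: str  # tukey | dunnett | sidak | bonferroni
    pairs: tuple[tuple[str, str], ...]
    p_adj: tuple[float, ...]
    estimates: tuple[float, ...] = ()

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(zip(self.pairs, self.p_adj))


@dataclass(frozen=True)
class ICCResult:
    model: str
    value: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    t: float
    df: int
    p: float


def sidak_adjust(p: float, m: int) -> float:
    """Šidák adjustment for ``m`` independent comparisons."""
    return float(1.0 - (1.0 - p) ** m)


# ---------------------------------------------------------------------------
# response profiles


def response_profile(
    changes: pd.DataFrame, condition: str, m: int
) -> dict[str, TTestResult]:
    """One-sample t tests of proportional change against zero, per parameter.

    ``m`` is the number of comparisons performed in the experiment (read
    from the experimental design); raw p values are Bonferroni-adjusted as
    ``min(1, m * p)``.

    Raises
    ------
    DegenerateSampleError
        For a parameter with < 2 defined changes or zero variance.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    sel = changes[changes["condition"] == condition]
    out: dict[str, TTestResult] = {}
    for name in PARAMETER_NAMES:
        if name not in sel.columns:
            continue
        values = sel[name].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if len(values) < 2:
            raise DegenerateSampleError(
                f"{name}: need >= 2 defined changes, got {len(values)}"
            )
        if np.ptp(values) == 0.0 and values[0] != 0.0:
            raise DegenerateSampleError(f"{name}: degenerate sample (zero variance)")
        if np.ptp(values) == 0.0:
            # all exactly zero: no change, t = 0 by convention
            t_stat, p_raw = 0.0, 1.0
        else:
            t_stat, p_raw = sps.ttest_1samp(values, 0.0)
        out[name] = TTestResult(
            t=float(t_stat),
            df=float(len(values) - 1),
            p_raw=float(p_raw),
            p_adj=float(min(1.0, m * p_raw)),
            m=m,
        )
    return out


# ---------------------------------------------------------------------------
# ANOVAs


def one_way_anova(
    units: pd.DataFrame, value: str, group: str
) -> tuple[AnovaResult, PosthocResult]:
    """Between-groups one-way ANOVA with Tukey HSD on all pairs.

    Subject repetition is deliberately not modelled: pooled designs need
    not expose every animal to every stimulus.
    """
    levels = list(pd.unique(units[group]))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = []
    for lev in levels:
        vals = units.loc[units[group] == lev, value].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(f"group {lev!r} has < 2 observations")
        samples.append(vals)
    F, p = sps.f_oneway(*samples)
    k = len(samples)
    N = sum(map(len, samples))
    anova = AnovaResult(effect=group, F=float(F), df1=k - 1, df2=N - k, p=float(p))
    hsd = sps.tukey_hsd(*samples)
    pairs, p_adj, est = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append((str(levels[i]), str(levels[j])))
            p_adj.append(float(hsd.pvalue[i, j]))
            est.append(float(np.mean(samples[i]) - np.mean(samples[j])))
    posthoc = PosthocResult("tukey", tuple(pairs), tuple(p_adj), tuple(est))
    return anova, posthoc


def _tukey_posthoc(df: pd.DataFrame, value: str, factor: str) -> PosthocResult:
    levels = list(pd.unique(df[factor]))
    samples = [
        df.loc[df[factor] == lev, value].to_numpy(dtype=float) for lev in levels
    ]
    hsd = sps.tukey_hsd(*samples)
    pairs, p_adj, est = [], [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            pairs.append((str(levels[i]), str(levels[j])))
            p_adj.append(float(hsd.pvalue[i, j]))
            est.append(float(np.mean(samples[i]) - np.mean(samples[j])))
    return PosthocResult("tukey", tuple(pairs), tuple(p_adj), tuple(est))


def _sidak_cells(
    df: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> PosthocResult:
    """Šidák-adjusted pairwise comparisons of factor_a levels within each
    level of factor_b (simple effects after a significant interaction)."""
    pairs, p_adj, est = [], [], []
    comparisons = []
    for b_lev in pd.unique(df[factor_b]):
        cell = df[df[factor_b] == b_lev]
        a_levels = list(pd.unique(cell[factor_a]))
        for i in range(len(a_levels)):
            for j in range(i + 1, len(a_levels)):
                x = cell.loc[cell[factor_a] == a_levels[i], value].to_numpy(float)
                y = cell.loc[cell[factor_a] == a_levels[j], value].to_numpy(float)
                t, p = sps.ttest_ind(x, y, equal_var=False)
                comparisons.append(
                    (
                        (f"{a_levels[i]}|{b_lev}", f"{a_levels[j]}|{b_lev}"),
                        float(p),
                        float(np.mean(x) - np.mean(y)),
                    )
                )
    m = len(comparisons)
    for pair, p, d in comparisons:
        pairs.append(pair)
        p_adj.append(sidak_adjust(p, m))
        est.append(d)
    return PosthocResult("sidak", tuple(pairs), tuple(p_adj), tuple(est))


def two_way_anova(
    units: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    repeated_on: Optional[str] = None,
    subject: str = "animal_id",
    alpha: float = 0.05,
) -> tuple[list[AnovaResult], PosthocResult]:
    """Two-way ANOVA: main effects and interaction, with post hocs.

    With ``repeated_on`` set to one factor, a mixed design is fitted
    (between-subject factor + within-subject factor), applying a
    Greenhouse–Geisser correction when the repeated factor has more than
    two levels.  Post hoc policy: Tukey on the repeated/main factor when
    only main effects are significant; Šidák simple-effect comparisons
    when the interaction is significant.

    Fully between-subject designs use a Type II sum-of-squares
    decomposition (robust to mild imbalance).
    """
    if repeated_on is None:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        data = units.rename(
            columns={value: "_dv", factor_a: "_fa", factor_b: "_fb"}
        )
        model = ols("_dv ~ C(_fa) * C(_fb)", data=data).fit()
        table = sm.stats.anova_lm(model, typ=2)
        effects = []
        names = {"C(_fa)": factor_a, "C(_fb)": factor_b, "C(_fa):C(_fb)": "interaction"}
        for key, label in names.items():
            row = table.loc[key]
            effects.append(
                AnovaResult(
                    effect=label,
                    F=float(row["F"]),
                    df1=float(row["df"]),
                    df2=float(table.loc["Residual", "df"]),
                    p=float(row["PR(>F)"]),
                )
            )
        interaction_p = effects[-1].p
        if interaction_p < alpha:
            posthoc = _sidak_cells(units, value, factor_a, factor_b)
        else:
            posthoc = _tukey_posthoc(units, value, factor_a)
        return effects, posthoc

    import pingouin as pg

    within = repeated_on
    between = factor_b if repeated_on == factor_a else factor_a
    n_within = units[within].nunique()
    table = pg.mixed_anova(
        data=units,
        dv=value,
        within=within,
        subject=subject,
        between=between,
        correction=(n_within > 2),
    )
    effects = []
    for _, row in table.iterrows():
        label = "interaction" if row["Source"] == "Interaction" else str(row["Source"])
        eps = None
        p = float(row["p_unc"])
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        if row["Source"] == within:
            if n_within > 2 and "eps" in table.columns and np.isfinite(row.get("eps", np.nan)):
                eps = float(row["eps"])
                df1, df2 = df1 * eps, df2 * eps
                if "p_GG_corr" in table.columns and np.isfinite(
                    row.get("p_GG_corr", np.nan)
                ):
                    p = float(row["p_GG_corr"])
            else:
                eps = 1.0  # two levels: sphericity holds trivially
        effects.append(
            AnovaResult(effect=label, F=float(row["F"]), df1=df1, df2=df2, p=p, epsilon=eps)
        )
    interaction_p = next(e.p for e in effects if e.effect == "interaction")
    if interaction_p < alpha:
        posthoc = _sidak_cells(units, value, within, between)
    else:
        posthoc = _tukey_posthoc(units, value, within)
    return effects, posthoc


# ---------------------------------------------------------------------------
# repeated measures + Dunnett


def dunnett_rm_pvalues(
    wide: np.ndarray,
    control: int = 0,
    random_state: int = 0,
    maxpts_per_dim: int = 20_000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Dunnett many-to-one comparisons for a repeated-measures design.

    ``wide`` is subjects x levels.  Each non-control level is compared with
    the control using the repeated-measures error mean square; adjusted
    two-sided p values come from the equicorrelated (rho = 1/2)
    multivariate t distribution integrated numerically, the same family of
    quantiles printed in Dunnett tables.

    Returns ``(t_statistics, adjusted_p, error_df)``.
    """
    wide = np.asarray(wide, dtype=float)
    n, k = wide.shape
    grand = wide.mean()
    subj_means = wide.mean(axis=1, keepdims=True)
    level_means = wide.mean(axis=0, keepdims=True)
    resid = wide - subj_means - level_means + grand
    df_err = (n - 1) * (k - 1)
    mse = float((resid**2).sum() / df_err)
    se = math.sqrt(2.0 * mse / n)
    others = [j for j in range(k) if j != control]
    diffs = wide[:, others].mean(axis=0) - wide[:, control].mean()
    if se == 0.0:
        t_stats = np.zeros(len(others))
        return t_stats, np.ones(len(others)), float(df_err)
    t_stats = diffs / se
    m = len(others)
    corr = np.full((m, m), 0.5)
    np.fill_diagonal(corr, 1.0)
    mvt = sps.multivariate_t(loc=np.zeros(m), shape=corr, df=df_err)
    p_adj = np.empty(m)
    for i, t in enumerate(t_stats):
        c = abs(float(t))
        if c == 0.0:
            p_adj[i] = 1.0
            continue
        inside = mvt.cdf(
            np.full(m, c),
            lower_limit=np.full(m, -c),
            random_state=random_state,
            maxpts=maxpts_per_dim * m,
        )
        p_adj[i] = min(1.0, max(0.0, 1.0 - float(inside)))
    return t_stats, p_adj, float(df_err)


def rm_anova_dunnett(
    bins: pd.DataFrame,
    value: str,
    within: str = "bin_label",
    subject: str = "animal_id",
    control: str = "baseline",
) -> tuple[AnovaResult, PosthocResult]:
    """Repeated-measures ANOVA over temporal bins + Dunnett vs baseline.

    Subjects missing any bin are dropped with a warning; fewer than three
    complete subjects is an error.  The within-subject F carries a
    Greenhouse–Geisser correction (fractional degrees of freedom) when the
    factor has more than two levels.
    """
    import pingouin as pg

    levels = list(pd.unique(bins[within]))
    if control not in levels:
        raise ValueError(f"control level {control!r} absent from {within!r}")
    wide = bins.pivot_table(index=subject, columns=within, values=value, aggfunc="mean")
    wide = wide.reindex(columns=levels)
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(
            f"rm_anova_dunnett: dropped {n_dropped} subject(s) with missing bins",
            stacklevel=2,
        )
    if len(complete) < 3:
        raise ValueError("need >= 3 complete subjects")
    long = complete.reset_index().melt(
        id_vars=subject, var_name=within, value_name="_dv"
    )
    k = len(levels)
    if np.allclose(complete.to_numpy().var(axis=0).sum(), 0.0) or np.allclose(
        complete.to_numpy() - complete.to_numpy()[:, [0]], 0.0
    ):
        # all levels identical within each subject: F = 0 by definition
        n = len(complete)
        anova = AnovaResult(
            effect=within, F=0.0, df1=k - 1, df2=(n - 1) * (k - 1), p=1.0, epsilon=1.0
        )
    else:
        table = pg.rm_anova(
            data=long, dv="_dv", within=within, subject=subject, correction=(k > 2)
        )
        row = table.iloc[0]
        eps = float(row["eps"]) if k > 2 and "eps" in table.columns else 1.0
        p = float(row["p_GG_corr"]) if "p_GG_corr" in table.columns and np.isfinite(
            row.get("p_GG_corr", np.nan)
        ) else float(row["p_unc"])
        anova = AnovaResult(
            effect=within,
            F=float(row["F"]),
            df1=float(row["ddof1"]) * eps,
            df2=float(row["ddof2"]) * eps,
            p=p,
            epsilon=eps,
        )
    ctrl_idx = levels.index(control)
    t_stats, p_adj, _ = dunnett_rm_pvalues(complete.to_numpy(), control=ctrl_idx)
    others = [lev for lev in levels if lev != control]
    pairs = tuple((str(lev), str(control)) for lev in others)
    posthoc = PosthocResult(
        "dunnett", pairs, tuple(map(float, p_adj)), tuple(map(float, t_stats))
    )
    return anova, posthoc


# ---------------------------------------------------------------------------
# reliability & controls


def icc(ratings: pd.DataFrame | np.ndarray) -> ICCResult:
    """Inter-observer ICC(2,1): two-way random effects, absolute agreement,
    single measure.

    ``ratings`` is an items x raters matrix (frames as rows, observers as
    columns); missing cells are removed listwise.

    Raises
    ------
    DegenerateSampleError
        With constant ratings across items (the coefficient is undefined).
    """
    mat = pd.DataFrame(ratings).dropna()
    n, k = mat.shape
    if k < 2 or n < 5:
        raise ValueError("need >= 2 raters and >= 5 items")
    if np.ptp(mat.to_numpy()) == 0.0:
        raise DegenerateSampleError("constant ratings: ICC undefined")
    import pingouin as pg

    long = mat.reset_index(names="_item").melt(
        id_vars="_item", var_name="_rater", value_name="_score"
    )
    table = pg.intraclass_corr(
        data=long, targets="_item", raters="_rater", ratings="_score"
    ).set_index("Type")
    # two-way random effects, absolute agreement, single measure
    row = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
    ci = row["CI95"] if "CI95" in row.index else row["CI95%"]
    return ICCResult(
        model="two-way random, absolute agreement, single measure (ICC2,1)",
        value=float(row["ICC"]),
        ci_lower=float(ci[0]),
        ci_upper=float(ci[1]),
    )


def pearson_control(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of a covariate (age, weight, ...) with a parameter.

    Reports rho, t = rho * sqrt(df / (1 - rho^2)) with df = n - 2, and the
    two-sided p value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateSampleError("zero variance in x or y")
    rho, p = sps.pearsonr(x, y)
    df = len(x) - 2
    if abs(rho) >= 1.0:
        t = math.copysign(math.inf, rho)
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
    return CorrelationResult(rho=float(rho), t=float(t), df=df, p=float(p))


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance two-sample t test (Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:  # identical constants: no difference by definition
            return TTestResult(t=0.0, df=float(len(a) + len(b) - 2), p_raw=1.0, p_adj=1.0)
        raise DegenerateSampleError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        p_adj=float(res.pvalue),
    )
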