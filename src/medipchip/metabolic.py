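"""Phenotype and expression statistics for the 2x2 diet design.

Covers the insulin-resistance index HOMA-IR, trapezoidal OGTT glucose AUC,
relative expression by the comparative Ct method (2^-ddCt), two-way
factorial ANOVA (maternal diet x offspring diet) and a Welch t test from
summary statistics.

Units matter and are fixed by convention here: glucose in mmol/L, insulin
in uIU/mL, OGTT time in minutes (AUC therefore in mmol/L*min), Ct in PCR
cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

OGTT_TIMES = (0, 30, 60, 120)
HOMA_DENOMINATOR = 22.5


def homa_ir(glucose, insulin):
    """HOMA-IR = fasting glucose [mmol/L] x fasting insulin [uIU/mL] / 22.5
    (Matthews' formulation)."""
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("glucose and insulin must be strictly positive")
    out = g * i / HOMA_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def ogtt_auc(glucose, times=OGTT_TIMES, incremental: bool = False):
    """Trapezoidal area under the glucose-vs-time curve.

    Total AUC by default; ``incremental=True`` integrates the excursion
    above the time-0 baseline instead (may be negative, not clipped).
    Accepts a single series or a 2-D array (rows = animals).
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if g.shape[-1] != t.shape[0]:
        raise ValueError(f"glucose series length {g.shape[-1]} != number of times {t.shape[0]}")
    if incremental:
        g = g - g[..., :1]
    out = np.trapezoid(g, t, axis=-1)
    return float(out) if out.ndim == 0 else out


def ddct(ct: pd.DataFrame, calibrator: str = "CON-CON",
         target_col: str = "target_ct", reference_col: str = "reference_ct",
         group_col: str = "group") -> pd.DataFrame:
    """Comparative Ct relative expression.

    dCt = Ct_target - Ct_reference per sample; ddCt = dCt - mean dCt of the
    calibrator group; fold = 2^-ddCt.  By construction the geometric mean
    fold of the calibrator group is exactly 1.
    """
    for col in (target_col, reference_col, group_col):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    bad = ct.index[ct[reference_col].isna() | ct[target_col].isna()]
    if len(bad):
        raise ValueError(f"missing Ct value for sample(s): {list(bad)}")
    cal = ct[ct[group_col] == calibrator]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator!r} is empty")
    out = ct.copy()
    out["dct"] = out[target_col] - out[reference_col]
    cal_mean = out.loc[out[group_col] == calibrator, "dct"].mean()
    out["ddct"] = out["dct"] - cal_mean
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out


@dataclass
class AnovaResult:
    """Two-way ANOVA table: rows factor_a, factor_b, interaction, residual
    with columns ss, df, F, p.  F and p are NaN for a degenerate response
    (SS_total == 0), reported as not-applicable rather than an error."""

    table: pd.DataFrame
    ss_total: float
    balanced: bool

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])


def _balanced_anova(values, fa, fb, a_levels, b_levels, n) -> AnovaResult:
    """Textbook partitioned sums of squares for a balanced a x b design."""
    a, b = len(a_levels), len(b_levels)
    cell = np.empty((a, b), dtype=object)
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            cell[i, j] = values[(fa == al) & (fb == bl)]
    grand = values.mean()
    cell_means = np.array([[cell[i, j].mean() for j in range(b)] for i in range(a)])
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)
    ss_a = n * b * float(np.sum((a_means - grand) ** 2))
    ss_b = n * a * float(np.sum((b_means - grand) ** 2))
    ss_ab = n * float(np.sum((cell_means - a_means[:, None] - b_means[None, :] + grand) ** 2))
    ss_e = float(sum(np.sum((cell[i, j] - cell_means[i, j]) ** 2)
                     for i in range(a) for j in range(b)))
    ss_total = float(np.sum((values - grand) ** 2))
    df = {"factor_a": a - 1, "factor_b": b - 1,
          "interaction": (a - 1) * (b - 1), "residual": a * b * (n - 1)}
    ms_e = ss_e / df["residual"]
    rows = {}
    for term, ss in (("factor_a", ss_a), ("factor_b", ss_b), ("interaction", ss_ab)):
        if ss_total == 0.0 or ms_e == 0.0:
            f_val, p_val = float("nan"), float("nan")
        else:
            f_val = (ss / df[term]) / ms_e
            p_val = float(stats.f.sf(f_val, df[term], df["residual"]))
        rows[term] = {"ss": ss, "df": df[term], "F": f_val, "p": p_val}
    rows["residual"] = {"ss": ss_e, "df": df["residual"], "F": float("nan"), "p": float("nan")}
    return AnovaResult(table=pd.DataFrame(rows).T, ss_total=ss_total, balanced=True)


def _type2_anova(values, fa, fb) -> AnovaResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": values, "a": fa, "b": fb})
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    mapping = {"C(a)": "factor_a", "C(b)": "factor_b",
               "C(a):C(b)": "interaction", "Residual": "residual"}
    out = tab.rename(index=mapping).rename(
        columns={"sum_sq": "ss", "PR(>F)": "p"})[["ss", "df", "F", "p"]]
    ss_total = float(np.sum((values - values.mean()) ** 2))
    return AnovaResult(table=out.loc[["factor_a", "factor_b", "interaction", "residual"]],
                       ss_total=ss_total, balanced=False)


def twoway_anova(values, factor_a, factor_b) -> AnovaResult:
    """Two-way crossed ANOVA with interaction.

    Balanced designs use the exact textbook SS partition (SS_A + SS_B +
    SS_AB + SS_resid == SS_total); unbalanced designs fall back to Type-II
    sums of squares.  Every cell must contain at least 2 observations.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(values) == len(fa) == len(fb)):
        raise ValueError("values and factor labels must have equal length")
    a_levels = list(dict.fromkeys(fa))
    b_levels = list(dict.fromkeys(fb))
    sizes = {}
    for al in a_levels:
        for bl in b_levels:
            k = int(np.sum((fa == al) & (fb == bl)))
            if k == 0:
                raise ValueError(f"empty cell: ({al!r}, {bl!r})")
            if k < 2:
                raise ValueError(f"cell ({al!r}, {bl!r}) has fewer than 2 observations; "
                                 "interaction term is undefined")
            sizes[(al, bl)] = k
    ns = set(sizes.values())
    if len(ns) == 1:
        return _balanced_anova(values, fa, fb, a_levels, b_levels, ns.pop())
    return _type2_anova(values, fa, fb)


class SummaryTTest(NamedTuple):
    t: float
    df: float
    p: float


def t_from_summary(mean1: float, dispersion1: float, n1: int,
                   mean2: float, dispersion2: float, n2: int,
                   dispersion_kind: str = "sd") -> SummaryTTest:
    """Welch t test from group summary statistics.

    ``dispersion_kind`` selects whether the dispersions are standard
    deviations ("sd") or standard errors of the mean ("sem"; converted
    internally via SD = SEM * sqrt(n)).  Satterthwaite degrees of freedom;
    two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if dispersion1 <= 0 or dispersion2 <= 0:
        raise ValueError("dispersions must be strictly positive")
    kind = dispersion_kind.lower()
    if kind == "sem":
        sd1, sd2 = dispersion1 * np.sqrt(n1), dispersion2 * np.sqrt(n2)
    elif kind == "sd":
        sd1, sd2 = dispersion1, dispersion2
    else:
        raise ValueError(f"dispersion_kind must be 'sd' or 'sem', got {dispersion_kind!r}")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return SummaryTTest(t=float(t), df=float(df), p=p)


def phenotype_summary(pheno: pd.DataFrame) -> pd.DataFrame:
    """Derive HOMA-IR and OGTT AUC per animal and run the two-way ANOVA for
    every trait.  Returns a tidy table of F and p per trait x term."""
    df = pheno.copy()
    if {"fasting_glucose", "fasting_insulin"} <= set(df.columns):
        df["homa_ir"] = homa_ir(df["fasting_glucose"], df["fasting_insulin"])
    ogtt_cols = [f"ogtt_glucose_{t}" for t in OGTT_TIMES]
    if set(ogtt_cols) <= set(df.columns):
        df["ogtt_auc"] = ogtt_auc(df[ogtt_cols].to_numpy(), OGTT_TIMES)
    meta = {"animal_id", "maternal_diet", "offspring_diet"}
    traits = [c for c in df.columns if c not in meta]
    rows = []
    for trait in traits:
        res = twoway_anova(df[trait].to_numpy(),
                           df["maternal_diet"].to_numpy(),
                           df["offspring_diet"].to_numpy())
        for term in ("factor_a", "factor_b", "interaction"):
            label = {"factor_a": "maternal_diet", "factor_b": "offspring_diet",
                     "interaction": "maternal_x_offspring"}[term]
            rows.append({"trait": trait, "term": label,
                         "F": res.f(term), "p": res.p(term)})
    return pd.DataFrame(rows)
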