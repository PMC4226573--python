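"""SBP categorization and two-way (sex × SBP category) ANOVA.

Subjects are binned into four SBP categories (≤110, 111–120, 121–130,
≥131 mmHg; readings rounded to integers first) and each variable is
analyzed with a two-way fixed-effects ANOVA: main effects of sex and SBP
category plus their interaction, on the unbalanced layout.  Sums of squares
are Type III with sum-to-zero factor coding by default (Type II available),
via statsmodels OLS.  Significance is bucketed as NS / P<0.05 / P<0.01 with
the a-priori threshold at 0.05.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DesignError, InputError

SBP_CATEGORIES = ("<=110", "111-120", "121-130", ">=131")

EFFECTS = ("sex", "sbp_category", "interaction")


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: float
    df_den: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    @property
    def bucket(self) -> str:
        if self.p < 0.01:
            return "P<0.01"
        if self.p < 0.05:
            return "P<0.05"
        return "NS"


@dataclass(frozen=True)
class AnovaResult:
    """F, degrees of freedom and p-value per effect for one response."""

    response: str
    effects: dict[str, EffectResult]

    def __getitem__(self, effect: str) -> EffectResult:
        return self.effects[effect]


def assign_sbp_category(sbp: float) -> str:
    """Bin an SBP reading (mmHg) into its category.

    The reading is rounded to an integer first (half-to-even, so 130.5 stays
    in the 121–130 band; auscultatory pressures are integer-valued in
    practice), then binned with inclusive boundaries: ≤110, 111–120,
    121–130, ≥131.
    """
    if not sbp > 0:
        raise InputError(f"SBP must be positive, got {sbp}")
    v = round(float(sbp))
    if v <= 110:
        return SBP_CATEGORIES[0]
    if v <= 120:
        return SBP_CATEGORIES[1]
    if v <= 130:
        return SBP_CATEGORIES[2]
    return SBP_CATEGORIES[3]


def _check_design(table: pd.DataFrame) -> None:
    for factor in ("sex", "sbp_category"):
        if factor not in table.columns:
            raise InputError(f"table lacks factor column {factor!r}")
        if table[factor].isna().any():
            raise InputError(f"missing labels in factor {factor!r}")
    sexes = pd.unique(table["sex"].astype(str))
    cats = pd.unique(table["sbp_category"].astype(str))
    if len(sexes) < 2 or len(cats) < 2:
        raise DesignError("need at least 2 observed levels per factor")
    counts = table.groupby(
        [table["sex"].astype(str), table["sbp_category"].astype(str)], observed=False
    ).size()
    full = counts.reindex(pd.MultiIndex.from_product([sexes, cats]), fill_value=0)
    if (full == 0).any():
        empty = [tuple(i) for i in full[full == 0].index]
        raise DesignError(f"empty design cells make the layout rank-deficient: {empty}")


def two_way_anova(table: pd.DataFrame, response: str, ss_type: int = 3) -> AnovaResult:
    """Two-way fixed-effects ANOVA of ``response`` on sex × SBP category.

    Type III sums of squares with sum-to-zero coding by default
    (``ss_type=2`` for Type II).  A response with zero variance returns
    F = 0, p = 1 for every effect (the 0/0 degenerate case).
    """
    _check_design(table)
    if response not in table.columns:
        raise InputError(f"unknown response column {response!r}")
    if ss_type not in (2, 3):
        raise InputError("ss_type must be 2 or 3")

    df = table[["sex", "sbp_category", response]].copy()
    df["sex"] = df["sex"].astype(str)
    df["sbp_category"] = df["sbp_category"].astype(str)
    y = df[response].to_numpy(dtype=float)
    n = len(df)
    n_cells = df.groupby(["sex", "sbp_category"]).ngroups
    df_den = float(n - n_cells)

    if np.ptp(y) == 0.0:
        zero = lambda d: EffectResult(F=0.0, df_num=d, df_den=df_den, p=1.0)
        k_sex = df["sex"].nunique() - 1
        k_cat = df["sbp_category"].nunique() - 1
        return AnovaResult(
            response=response,
            effects={
                "sex": zero(float(k_sex)),
                "sbp_category": zero(float(k_cat)),
                "interaction": zero(float(k_sex * k_cat)),
            },
        )

    formula = f"Q('{response}') ~ C(sex, Sum) * C(sbp_category, Sum)"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = sm.stats.anova_lm(model, typ=ss_type)

    keymap = {
        "C(sex, Sum)": "sex",
        "C(sbp_category, Sum)": "sbp_category",
        "C(sex, Sum):C(sbp_category, Sum)": "interaction",
    }
    effects = {}
    for row_name, effect in keymap.items():
        row = tab.loc[row_name]
        effects[effect] = EffectResult(
            F=float(row["F"]),
            df_num=float(row["df"]),
            df_den=float(tab.loc["Residual", "df"]),
            p=float(row["PR(>F)"]),
        )
    return AnovaResult(response=response, effects=effects)


def anova_report(table: pd.DataFrame, variables: list[str], ss_type: int = 3) -> pd.DataFrame:
    """Tidy ANOVA report: one row per (variable, effect)."""
    rows = []
    for var in variables:
        res = two_way_anova(table, var, ss_type=ss_type)
        for effect in EFFECTS:
            e = res[effect]
            rows.append(
                {
                    "variable": var,
                    "effect": effect,
                    "F": e.F,
                    "df1": e.df_num,
                    "df2": e.df_den,
                    "p": e.p,
                    "bucket": e.bucket,
                }
            )
    return pd.DataFrame(rows)


def group_summary(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Mean, SD and count per (sex × SBP category) cell per variable.

    SD uses the n-1 denominator; a single-subject cell reports SD 0 and
    triggers a warning.  Layout: one row per (sex, sbp_category) with
    ``<var>_mean`` / ``<var>_sd`` columns plus ``n``.
    """
    _check_design(table)
    grouped = table.groupby(
        [table["sex"].astype(str), table["sbp_category"].astype(str)], observed=True
    )
    rows = []
    for (sex, cat), sub in grouped:
        row = {"sex": sex, "sbp_category": cat, "n": len(sub)}
        if len(sub) == 1:
            warnings.warn(f"cell ({sex}, {cat}) has n=1; SD reported as 0", stacklevel=2)
        for var in variables:
            row[f"{var}_mean"] = float(sub[var].mean())
            row[f"{var}_sd"] = float(sub[var].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
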