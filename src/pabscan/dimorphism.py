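"""Sexual-dimorphism statistics from a species phenotype table.

Three standard log-ratio / residual statistics are computed per species and
summarised per group (haplorrhines vs strepsirrhines):

- SSD, size sexual dimorphism: ln(male body mass / female body mass)
- CSD, canine sexual dimorphism: ln(male canine height / female canine height)
- RTM, relative testes mass: residual of the OLS regression
  ln(combined testes mass) ~ ln(male body mass), fitted jointly across all
  species with both measurements (a sperm-competition proxy).

The body-mass column used for RTM is separate from the one used for SSD
because the two come from different literature sources and may differ for
the same species.

A reference phenotype table for 13 primate species (6 haplorrhines, 7
strepsirrhines) ships with the package; see :func:`load_reference_table`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_reference_table",
    "load_phenotype_table",
    "ssd",
    "csd",
    "relative_testes_mass",
    "group_summary",
    "group_compare",
    "ancova_testes",
]

REQUIRED_COLUMNS = [
    "species",
    "group",
    "male_mass_g",
    "female_mass_g",
    "male_canine_mm",
    "female_canine_mm",
    "testes_mass_g",
    "male_mass_for_testes_g",
]


def load_phenotype_table(path) -> pd.DataFrame:
    """Read a phenotype CSV (empty cells = missing) and check its columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return df


def load_reference_table() -> pd.DataFrame:
    """The packaged 13-primate phenotype table."""
    ref = importlib.resources.files("pabscan.data") / "table1_dimorphism.csv"
    with importlib.resources.as_file(ref) as path:
        return load_phenotype_table(path)


def _log_ratio(df: pd.DataFrame, male_col: str, female_col: str) -> pd.Series:
    """ln(male/female) per species; NaN where either value is missing."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log(df[male_col] / df[female_col])


def ssd(df: pd.DataFrame) -> pd.Series:
    """Size sexual dimorphism per species: ln(male mass / female mass)."""
    return _log_ratio(df, "male_mass_g", "female_mass_g").rename("ssd")


def csd(df: pd.DataFrame) -> pd.Series:
    """Canine sexual dimorphism per species: ln(male canine / female canine)."""
    return _log_ratio(df, "male_canine_mm", "female_canine_mm").rename("csd")


def relative_testes_mass(df: pd.DataFrame) -> pd.Series:
    """Per-species residual of OLS ln(testes mass) ~ ln(male body mass).

    The regression is fitted once across all species with both
    measurements (the sperm-competition male-mass column); species with a
    missing value get NaN.  Requires at least 3 complete records.
    """
    complete = df["testes_mass_g"].notna() & df["male_mass_for_testes_g"].notna()
    if complete.sum() < 3:
        raise ValueError(
            f"need >= 3 species with testes and male mass; have {int(complete.sum())}"
        )
    x = np.log(df.loc[complete, "male_mass_for_testes_g"].to_numpy(dtype=float))
    y = np.log(df.loc[complete, "testes_mass_g"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    out = pd.Series(np.nan, index=df.index, name="rtm")
    out.loc[complete] = y - (intercept + slope * x)
    return out


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    se: float  # sample SD / sqrt(n)


def group_summary(values: pd.Series, groups: pd.Series) -> dict[str, GroupSummary]:
    """Per-group mean and standard error over species with a defined value."""
    out: dict[str, GroupSummary] = {}
    for g, vals in values.groupby(groups):
        v = vals.dropna().to_numpy(dtype=float)
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        out[str(g)] = GroupSummary(str(g), int(v.size), float(v.mean()), se)
    return out


@dataclass(frozen=True)
class GroupComparison:
    test: str
    group_summaries: dict[str, GroupSummary]
    statistic: float
    p_value: float


def group_compare(
    values: pd.Series, groups: pd.Series, method: str = "welch"
) -> GroupComparison:
    """Two-sample comparison of a dimorphism statistic between groups.

    No phylogenetic correction is applied — species are treated as
    independent.  ``method`` is "welch" (unequal-variance t test, default)
    or "ranksum" (Mann-Whitney U).
    """
    summaries = group_summary(values, groups)
    names = sorted(summaries)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, have {names}")
    if any(summaries[g].n < 2 for g in names):
        raise ValueError("each group needs n >= 2 defined values")
    a = values[groups == names[0]].dropna().to_numpy(dtype=float)
    b = values[groups == names[1]].dropna().to_numpy(dtype=float)
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        label = "Welch two-sample t"
    elif method == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        label = "Mann-Whitney U"
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        test=label,
        group_summaries=summaries,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class AncovaResult:
    group_coefficient: float
    group_p_value: float
    slope: float
    intercept: float
    n: int
    reference_group: str
    other_group: str


def ancova_testes(df: pd.DataFrame) -> AncovaResult:
    """Analysis of covariance: ln(testes) ~ ln(male mass) + group.

    Ordinary least squares with the log male body mass as covariate and a
    group indicator; reports the group coefficient (effect of the
    non-reference group on log testes mass at equal body mass) and its
    t-test p-value.
    """
    complete = df["testes_mass_g"].notna() & df["male_mass_for_testes_g"].notna()
    sub = df.loc[complete]
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, have {groups}")
    x = np.log(sub["male_mass_for_testes_g"].to_numpy(dtype=float))
    y = np.log(sub["testes_mass_g"].to_numpy(dtype=float))
    ind = (sub["group"] == groups[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x, ind])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t_stat = beta[2] / np.sqrt(cov[2, 2])
    p = 2 * stats.t.sf(abs(t_stat), dof)
    return AncovaResult(
        group_coefficient=float(beta[2]),
        group_p_value=float(p),
        slope=float(beta[1]),
        intercept=float(beta[0]),
        n=len(y),
        reference_group=str(groups[0]),
        other_group=str(groups[1]),
    )
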