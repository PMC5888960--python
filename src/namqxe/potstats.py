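"""Pot-experiment statistics for a candidate locus.

Lines segregating at a peak marker are grouped into wild-allele carriers
(Hs/_ = Hs/Hs or Hv/Hs) versus the cultivated homozygote (Hv/Hv), then
compared by a two-way fixed-effects factorial ANOVA (drought treatment x
allelic state, with interaction; Type-II sums of squares for unbalanced
cells).  Group differences are summarised with compact letter displays
from pairwise Student's t or Tukey-Kramer tests, and treatment effects as
percent reductions relative to the well-watered mean.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "group_alleles",
    "factorial_anova",
    "pairwise_pvalues",
    "mean_letters",
    "percent_reduction",
]


def group_alleles(codes: pd.Series) -> pd.Series:
    """Map genotype codes at a marker to allele groups: 1 or 2 (carrying at
    least one wild allele) -> ``Hs/_``, 0 -> ``Hv/Hv``.  Lines with missing
    genotype are excluded with a warning."""
    codes = pd.Series(codes).astype(float)
    missing = codes.isna()
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} line(s) with missing genotype")
    codes = codes[~missing]
    bad = ~codes.isin([0.0, 1.0, 2.0])
    if bad.any():
        raise ValueError(f"invalid genotype codes: {sorted(codes[bad].unique())}")
    return codes.map({0.0: "Hv/Hv", 1.0: "Hs/_", 2.0: "Hs/_"}).rename("allele_group")


def factorial_anova(
    values: pd.Series | np.ndarray,
    treatment: pd.Series | np.ndarray,
    allele: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction (Type-II SS).

    Returns a table with rows treatment, allele, treatment:allele and
    residual (df, sum_sq, mean_sq, F, p).  If any treatment x allele cell is
    empty the interaction is dropped with a warning and a main-effects model
    is fitted.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "treatment": np.asarray(treatment, dtype=object),
            "allele": np.asarray(allele, dtype=object),
        }
    ).dropna()
    cells = df.groupby(["treatment", "allele"], sort=True).size()
    n_cells = df["treatment"].nunique() * df["allele"].nunique()
    with_interaction = len(cells) == n_cells
    if not with_interaction:
        warnings.warn("empty treatment x allele cell: interaction dropped")
    formula = "value ~ C(treatment) " + (
        "* C(allele)" if with_interaction else "+ C(allele)"
    )
    fit = smf.ols(formula, data=df).fit()
    if fit.ssr < 1e-12 * max(1.0, float(np.abs(df["value"]).max()) ** 2):
        warnings.warn("residual sum of squares is ~0; F statistics are unreliable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = sm.stats.anova_lm(fit, typ=2)
    rename = {
        "C(treatment)": "treatment",
        "C(allele)": "allele",
        "C(treatment):C(allele)": "treatment:allele",
        "Residual": "residual",
    }
    table = table.rename(index=rename)
    table.index.name = "term"
    table = table.rename(columns={"PR(>F)": "p", "mean_sq": "mean_sq"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    return table[["df", "sum_sq", "mean_sq", "F", "p"]]


def pairwise_pvalues(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    method: str = "t",
) -> pd.DataFrame:
    """Symmetric matrix of pairwise p-values between group means.

    ``method="t"`` is a two-sample Student's t-test per pair (pooled SD of
    that pair, matching per-figure comparisons); ``"tukey"`` is the
    Tukey-Kramer honestly-significant-difference test over all groups.
    """
    from scipy import stats

    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups, object)}).dropna()
    names = sorted(df["group"].unique())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    if method == "t":
        for a, b in itertools.combinations(names, 2):
            xa = df.loc[df["group"] == a, "value"]
            xb = df.loc[df["group"] == b, "value"]
            p = stats.ttest_ind(xa, xb, equal_var=True).pvalue
            p = 1.0 if np.isnan(p) else float(p)
            out.loc[a, b] = out.loc[b, a] = p
    elif method == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(df["value"], df["group"])
        for (a, b), p in zip(
            itertools.combinations(res.groupsunique, 2), res.pvalues
        ):
            out.loc[a, b] = out.loc[b, a] = float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def mean_letters(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    method: str = "t",
    alpha: float = 0.05,
) -> pd.Series:
    """Compact letter display: groups sharing a letter are not significantly
    different at ``alpha`` under the chosen pairwise test.

    Uses the insert-and-absorb algorithm on the pairwise significance
    matrix; letters are assigned in descending order of group mean.
    """
    pvals = pairwise_pvalues(values, groups, method=method)
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups, object)}).dropna()
    order = df.groupby("group")["value"].mean().sort_values(ascending=False).index.tolist()

    # insert-and-absorb: maintain letter groups (sets of mutually
    # non-different groups); each group must appear in a letter set with
    # every group it does not differ from
    letters: list[set] = [set()]
    for g in order:
        placed = False
        for ls in letters:
            if all(pvals.loc[g, other] >= alpha for other in ls):
                ls.add(g)
                placed = True
        if not placed:
            new = {g} | {
                other for other in order if other != g and pvals.loc[g, other] >= alpha
            }
            # the new set may only contain mutually compatible members
            new = _largest_compatible(new, g, pvals, alpha)
            letters.append(new)
    # absorb letter sets fully contained in another
    letters = [
        ls
        for i, ls in enumerate(letters)
        if ls and not any(i != j and ls < other for j, other in enumerate(letters))
    ]
    if not letters:
        letters = [set(order)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment = {g: "" for g in order}
    for letter, ls in zip(alphabet, letters):
        for g in order:
            if g in ls:
                assignment[g] += letter
    return pd.Series(assignment, name="letters")


def _largest_compatible(candidates: set, anchor, pvals: pd.DataFrame, alpha: float) -> set:
    keep = {anchor}
    for g in sorted(candidates - {anchor}):
        if all(pvals.loc[g, other] >= alpha for other in keep):
            keep.add(g)
    return keep


def percent_reduction(mean_reference: float, mean_stressed: float) -> float:
    """Percent reduction of a stressed mean relative to a reference mean,
    rounded to one decimal (round-half-even).

    E.g. grain numbers of 334 (WW) vs 221 (WL) give a 33.8% reduction.
    """
    if mean_reference == 0:
        raise ValueError("reference mean must be non-zero")
    value = 100.0 * (mean_reference - mean_stressed) / mean_reference
    return float(np.round(value, 1))
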