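"""Derived traits, cross-year adjustment, line means and summaries.

The pipeline order is fixed: derive ratio/difference traits on raw
within-year values first, then rescale each (trait, year) so year-level
means agree, then average the adjusted values across years per line and
environment.  Deriving before adjusting keeps the ratio trait (harvest
index) biologically meaningful; for the linear derived traits the two
orders commute anyway.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "derive_traits",
    "adjust_across_years",
    "line_means",
    "summarize",
    "trait_correlations",
]

KEY = ["line", "family", "year", "environment"]

#: derived trait -> (function of the wide frame, source traits)
_DERIVED = {
    "GFP": (lambda w: w["MAT"] - w["HEA"], ("MAT", "HEA")),
    "HI": (lambda w: w["PGY"] / w["TDM"].where(w["TDM"] != 0), ("PGY", "TDM")),
    "VDW": (lambda w: w["TDM"] - w["PGY"], ("TDM", "PGY")),
}


def _to_wide(table: pd.DataFrame) -> pd.DataFrame:
    dup = table.duplicated(subset=KEY + ["trait"])
    if dup.any():
        raise ValueError("more than one record per (line, year, environment, trait)")
    return table.pivot_table(
        index=KEY, columns="trait", values="value", aggfunc="first", dropna=False
    )


def _to_long(wide: pd.DataFrame) -> pd.DataFrame:
    long = wide.stack(future_stack=True).rename("value").reset_index()
    long = long.dropna(subset=["value"]).reset_index(drop=True)
    return long[KEY + ["trait", "value"]]


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Add grain-filling period GFP = MAT - HEA, harvest index HI = PGY/TDM,
    and vegetative dry weight VDW = TDM - PGY where the source traits are
    present.  A zero TDM yields a missing HI with a warning; missing sources
    yield missing derived values.
    """
    wide = _to_wide(table)
    for name, (fn, sources) in _DERIVED.items():
        if all(s in wide.columns for s in sources):
            if name == "HI" and (wide["TDM"] == 0).any():
                warnings.warn("TDM = 0 encountered: HI set to missing for those records")
            wide[name] = fn(wide)
    return _to_long(wide)


def adjust_across_years(
    table: pd.DataFrame, stratify_environment: bool = False
) -> pd.DataFrame:
    """Rescale each (trait, year) by mean-over-all-years / mean-of-that-year.

    Every value of a trait in a year is multiplied by
    ``1 / (year mean / all-year mean)``, which equalises per-year trait
    means while preserving within-year contrasts.  By default the year
    means pool both watering environments; ``stratify_environment``
    computes and applies the factor per (trait, environment, year).
    Idempotent: a second application finds all factors equal to 1.
    """
    out = table.copy()
    strata = ["trait", "environment"] if stratify_environment else ["trait"]
    for keys, sub in out.groupby(strata):
        grand = sub["value"].mean()
        for year, ysub in sub.groupby("year"):
            ymean = ysub["value"].mean()
            if not np.isfinite(ymean) or ymean == 0:
                trait = keys[0] if isinstance(keys, tuple) else keys
                raise ValueError(
                    f"cannot adjust trait {trait!r}, year {year}: zero or undefined year mean"
                )
            out.loc[ysub.index, "value"] = ysub["value"] * (grand / ymean)
    return out


def line_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean value per (line, family, environment, trait) across the years in
    which the line was observed.  These per-line adjusted means are the
    response used in the genome scans."""
    out = (
        table.groupby(["line", "family", "environment", "trait"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    return out


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per (trait, environment): n, mean, SD and coefficient of variation
    CV = 100 * SD / mean."""
    g = table.groupby(["trait", "environment"])["value"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    out["cv"] = 100.0 * out["sd"] / out["mean"]
    return out


def trait_correlations(table: pd.DataFrame, environment: str) -> pd.DataFrame:
    """Pearson correlation matrix between traits within one environment,
    computed per line-mean on pairwise-complete observations.  Constant
    traits get missing correlations."""
    sub = table[table["environment"] == environment]
    wide = sub.pivot_table(index="line", columns="trait", values="value", aggfunc="mean")
    return wide.corr(method="pearson", min_periods=2)
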