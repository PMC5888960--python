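"""Genotype/map/phenotype file IO, marker-quality filters, and kinship.

File dialects (all tab-separated, plain text):

* genotype file — header row of marker ids; first two columns ``line`` and
  ``family``; cells in {0, 1, 2, NA}.
* map file — columns ``marker``, ``chromosome``, ``position_cm``.
* phenotype file — long format with columns ``line``, ``family``, ``year``,
  ``environment`` (WW/WL), ``trait``, ``value``.

Marker filters reproduce the panel's quality rules: keep markers that are
polymorphic in at least one family, have <10% missing calls, and are not in
complete linkage disequilibrium with an earlier marker in map order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .population import GENOTYPE_CODES, Population, validate_linkage_map

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "FilterReport",
    "filter_markers",
    "compute_kinship",
]

PHENOTYPE_COLUMNS = ["line", "family", "year", "environment", "trait", "value"]


# ---------------------------------------------------------------------------
# IO

def write_map(linkage_map: pd.DataFrame, path) -> None:
    validate_linkage_map(linkage_map).to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    return validate_linkage_map(pd.read_csv(path, sep="\t"))


def write_genotypes(pop: Population, path, map_path=None) -> None:
    """Write the genotype matrix; optionally the map alongside it."""
    out = pop.genotypes.copy()
    out.insert(0, "family", pop.families)
    out.index.name = "line"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")
    if map_path is not None:
        write_map(pop.linkage_map, map_path)


def read_genotypes(path, map_path=None, linkage_map: pd.DataFrame | None = None) -> Population:
    """Read a genotype file; the map comes from ``map_path`` or
    ``linkage_map``, or is synthesized (one chromosome, 1-cM spacing in
    column order) if neither is given."""
    df = pd.read_csv(path, sep="\t", index_col="line", na_values=["NA"])
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()]
        raise ValueError(f"duplicated line id(s): {list(dupes[:5])}")
    if "family" not in df.columns:
        raise ValueError("genotype file lacks a 'family' column")
    fam = df["family"]
    geno = df.drop(columns=["family"]).astype(float)
    vals = geno.to_numpy()
    bad = ~(np.isnan(vals) | np.isin(vals, GENOTYPE_CODES))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {vals[r, c]!r} at line {geno.index[r]!r}, "
            f"marker {geno.columns[c]!r}"
        )
    if map_path is not None:
        linkage_map = read_map(map_path)
    if linkage_map is None:
        linkage_map = pd.DataFrame(
            {
                "marker": geno.columns,
                "chromosome": 1,
                "position_cm": np.arange(len(geno.columns), dtype=float),
            }
        )
    return Population(genotypes=geno, families=fam, linkage_map=linkage_map)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    return df[PHENOTYPE_COLUMNS]


# ---------------------------------------------------------------------------
# marker filters

@dataclass
class FilterReport:
    """Which markers each quality rule removed, in application order."""

    n_input: int
    monomorphic: list[str] = field(default_factory=list)
    high_missing: list[str] = field(default_factory=list)
    complete_ld: list[str] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.monomorphic) + len(self.high_missing) + len(self.complete_ld)

    def check(self) -> None:
        assert self.n_dropped + len(self.surviving) == self.n_input


def _ld_candidates(
    vals: np.ndarray, kept_idx: np.ndarray, r_screen: float = 0.8, chunk: int = 1024
) -> dict[int, set[int]]:
    """Candidate complete-LD pairs: mean-imputed Pearson r >= ``r_screen``.

    Two markers identical at all jointly non-missing lines can disagree only
    at cells one of them misses (< 10% each after the missingness filter),
    so their imputed correlation stays far above the screen except for
    near-monomorphic columns — those are all paired with each other.
    Every candidate pair is verified exactly afterwards.
    """
    sub = vals[:, kept_idx].copy()
    mu = np.nanmean(sub, axis=0)
    rr, cc = np.nonzero(np.isnan(sub))
    sub[rr, cc] = mu[cc]
    sub -= sub.mean(axis=0)
    sd = sub.std(axis=0)
    low_var = sd < 1e-12
    z = np.divide(sub, np.where(low_var, 1.0, sd), out=sub)
    z[:, low_var] = 0.0
    n = z.shape[0]
    out: dict[int, set[int]] = {}

    def add(a: int, b: int) -> None:
        ja, jb = int(kept_idx[a]), int(kept_idx[b])
        lo, hi = min(ja, jb), max(ja, jb)
        out.setdefault(hi, set()).add(lo)

    for start in range(0, z.shape[1], chunk):
        block = z[:, start : start + chunk]
        corr = block.T @ z / n
        a_loc, b_loc = np.nonzero(corr >= r_screen)
        for a, b in zip(a_loc + start, b_loc):
            if a < b:
                add(a, b)
    lv = np.nonzero(low_var)[0]
    for ii, a in enumerate(lv):
        for b in lv[ii + 1 :]:
            add(int(a), int(b))
    return out


def filter_markers(
    pop: Population,
    max_missing: float = 0.10,
    ld_min_overlap: float = 0.50,
) -> tuple[Population, FilterReport]:
    """Apply the three marker-quality rules, in this fixed order:

    1. drop markers monomorphic within every family (uninformative);
    2. drop markers with missing fraction >= ``max_missing`` (the "<10%
       missing" rule: strictly less than the threshold is kept);
    3. among markers with identical genotypes at every jointly non-missing
       line (complete LD; pairs must overlap at >= ``ld_min_overlap`` of
       lines to count), keep the first in map order.
    """
    geno = pop.genotypes
    vals = geno.to_numpy(dtype=float)
    markers = np.array(pop.markers)

    fam_codes = pop.families.to_numpy()
    poly = np.zeros(len(markers), dtype=bool)
    for f in pd.unique(fam_codes):
        sub = vals[fam_codes == f]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mn = np.nanmin(sub, axis=0)
            mx = np.nanmax(sub, axis=0)
        poly |= np.nan_to_num(mx - mn) > 0
    monomorphic = list(markers[~poly])
    keep = poly.copy()

    miss_frac = np.isnan(vals).mean(axis=0)
    high_missing = list(markers[keep & (miss_frac >= max_missing)])
    keep &= miss_frac < max_missing

    ld_dropped: list[str] = []
    kept_idx = np.nonzero(keep)[0]
    n = vals.shape[0]
    surviving_mask = keep.copy()
    candidates = _ld_candidates(vals, kept_idx)
    # greedy in map order: a marker is dropped iff it is in complete LD
    # (identical at every jointly non-missing line, with enough overlap)
    # with an earlier marker that was kept
    kept_set: set[int] = set()
    for j in kept_idx:
        col_j = vals[:, j]
        nm_j = ~np.isnan(col_j)
        dup = False
        for i in sorted(candidates.get(j, ())):
            if i not in kept_set:
                continue
            col_i = vals[:, i]
            both = ~np.isnan(col_i) & nm_j
            if both.sum() < ld_min_overlap * n:
                continue
            if np.array_equal(col_i[both], col_j[both]):
                dup = True
                break
        if dup:
            surviving_mask[j] = False
            ld_dropped.append(markers[j])
        else:
            kept_set.add(j)

    surviving = list(markers[surviving_mask])
    out_map = pop.linkage_map[pop.linkage_map["marker"].isin(surviving)].reset_index(drop=True)
    out = Population(
        genotypes=geno[surviving].copy(),
        families=pop.families.copy(),
        linkage_map=out_map,
    )
    report = FilterReport(
        n_input=len(markers),
        monomorphic=monomorphic,
        high_missing=high_missing,
        complete_ld=ld_dropped,
        surviving=surviving,
    )
    report.check()
    return out, report


# ---------------------------------------------------------------------------
# kinship

def compute_kinship(pop: Population, method: str = "allele-sharing") -> pd.DataFrame:
    """Marker-based relatedness matrix over lines.

    ``allele-sharing`` (default): K[a, b] = mean over markers of
    1 - |g_a - g_b| / 2, the proportion of alleles shared; exact on hand
    examples and bounded in [0, 1].  ``centered-cross-product``: VanRaden-
    style Z Z' / m on column-centred genotypes, rescaled so the mean
    diagonal is 1.  Missing codes are mean-imputed per marker for this
    computation only.
    """
    if pop.n_lines < 2:
        raise ValueError("kinship needs at least two lines")
    vals = pop.genotypes.to_numpy(dtype=float).copy()
    all_missing = np.isnan(vals).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"excluding {int(all_missing.sum())} all-missing marker(s) from kinship"
        )
        vals = vals[:, ~all_missing]
    col_mean = np.nanmean(vals, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(vals))
    vals[nan_r, nan_c] = col_mean[nan_c]

    if method == "allele-sharing":
        # K[a,b] = mean_j (1 - |g_aj - g_bj| / 2); cityblock distance gives
        # the summed |g_a - g_b| term at C speed
        m = vals.shape[1]
        dist = squareform(pdist(vals, metric="cityblock"))
        k = 1.0 - dist / (2.0 * m)
    elif method == "centered-cross-product":
        z = vals - col_mean[None, :]
        k = z @ z.T / vals.shape[1]
        d = np.mean(np.diag(k))
        if d > 0:
            k = k / d
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    k = (k + k.T) / 2.0
    return pd.DataFrame(k, index=pop.genotypes.index, columns=pop.genotypes.index)
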