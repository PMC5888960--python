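"""Marker x environment interaction scan and the resampling acceptance rule.

The QxE model stacks each line's two environment records and fits

    y = mu + F_family + G_marker + E_env + (G x E) + u + eps

where the polygenic effect u is drawn once per line and shared by its two
records, giving the stacked covariance sigma2_g (K kron J2) + sigma2_e I
(J2 the 2x2 all-ones block).  The eigendecomposition of K kron J2 follows
directly from that of K, so the REML machinery of :mod:`namqxe.mmscan` is
reused unchanged.  The headline statistic is the joint F-test of the
genotype-class x environment interaction contrasts.

QTL acceptance follows the study's resampling rule: the scan is repeated on
random subsamples of 70% of the lines drawn within each family, and a
marker is accepted as a putative QTL when it reaches P < 0.05 in at least
30% of the replicates.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .mmscan import (
    KinshipEigen,
    _marker_dummies,
    design_matrices,
    fit_null_reml,
    scan_per_se,
)

__all__ = [
    "scan_qxe",
    "crossval",
    "window_peaks",
    "reaction_norms",
    "stack_environments",
]

ENVIRONMENTS = ("WW", "WL")


def stack_environments(pop, phenotypes: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Wide frame (line x {WW, WL}) of per-line means for ``trait``,
    restricted to lines observed in both environments, in population order."""
    sub = phenotypes[phenotypes["trait"] == trait].dropna(subset=["value"])
    envs = set(sub["environment"])
    if len(envs & set(ENVIRONMENTS)) < 2:
        raise ValueError(
            "phenotypes cover a single environment; use mmscan.scan_per_se instead"
        )
    wide = sub.pivot_table(index="line", columns="environment", values="value", aggfunc="mean")
    wide = wide.dropna(subset=list(ENVIRONMENTS))
    lines = [l for l in pop.genotypes.index if l in wide.index]
    return wide.loc[lines, list(ENVIRONMENTS)]


def _paired_eigen(eig: KinshipEigen) -> KinshipEigen:
    """Eigendecomposition of K kron J2 for line-major (WW, WL) record pairs:
    eigenvalues {2 s_i} and {0}, eigenvectors kron(U_i, (1,1)/sqrt2) and
    kron(U_i, (1,-1)/sqrt2)."""
    up = np.array([[1.0], [1.0]]) / np.sqrt(2.0)
    um = np.array([[1.0], [-1.0]]) / np.sqrt(2.0)
    U2 = np.hstack([np.kron(eig.U, up), np.kron(eig.U, um)])
    s2 = np.concatenate([2.0 * eig.s, np.zeros(eig.n)])
    return KinshipEigen.from_eigen(s2, U2)


def scan_qxe(
    pop,
    phenotypes: pd.DataFrame,
    trait: str,
    kinship: pd.DataFrame | None = None,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Genome scan for marker x environment interaction on one trait.

    Returns one row per marker with environment-specific Hs effects
    (relative to Hv/Hv, per environment), the joint interaction F statistic
    and p-value, and the marker's map position.  Variance components are
    estimated once on the no-marker null model (P3D) and re-used.
    """
    from .genodata import compute_kinship

    wide = stack_environments(pop, phenotypes, trait)
    lines = list(wide.index)
    sub = pop.subset_lines(lines)
    if kinship is None:
        kinship = compute_kinship(sub)
    eig1 = KinshipEigen(kinship.loc[lines, lines].to_numpy(float))
    eig2 = _paired_eigen(eig1)

    n = len(lines)
    # line-major stacking: records (line1 WW, line1 WL, line2 WW, ...)
    y = wide.to_numpy(float).ravel()
    env_wl = np.tile([0.0, 1.0], n)
    Xfam = design_matrices(sub.families)
    Xfam2 = np.repeat(Xfam, 2, axis=0)
    X0 = np.column_stack([Xfam2, env_wl])
    vc = fit_null_reml(y, X0, eig2)

    y_rot = eig2.rotate(y)
    yw = eig2.whiten(y_rot, vc.lam)
    Xw0 = eig2.whiten(eig2.rotate(X0), vc.lam)

    markers = markers if markers is not None else sub.markers
    # stacked covariance built once: needed only when markers have missing
    # calls (lines are then dropped and the whitening redone on the subset)
    K2 = None
    if sub.genotypes[markers].isna().to_numpy().any():
        K2 = np.kron(kinship.loc[lines, lines].to_numpy(float), np.ones((2, 2)))
    rows = []
    for m in markers:
        codes = sub.genotypes[m].to_numpy(float)
        rows.append(_test_qxe(y, X0, codes, env_wl, eig2, vc, yw, Xw0, K2))
        rows[-1]["marker"] = m
    out = pd.DataFrame(rows)
    out["trait"] = trait
    out["model"] = "qxe"
    cols = [
        "marker", "trait", "model",
        "effect_hshs_ww", "effect_hshs_wl", "effect_hvhs_ww", "effect_hvhs_wl",
        "fstat", "df1", "df2", "pvalue", "n", "monomorphic",
    ]
    return out[cols].merge(
        pop.linkage_map[["marker", "chromosome", "position_cm"]], on="marker", how="left"
    )


def _test_qxe(y, X0, codes, env_wl, eig2, vc, yw_full, Xw0_full, K2=None):
    """Joint F-test of the genotype-class x environment contrasts for one
    marker; reduced model keeps the marker main effect."""
    from scipy import stats

    n_lines = len(codes)
    rec_codes = np.repeat(codes, 2)
    ok = ~np.isnan(rec_codes)
    out = {
        "effect_hshs_ww": np.nan, "effect_hshs_wl": np.nan,
        "effect_hvhs_ww": np.nan, "effect_hvhs_wl": np.nan,
        "fstat": np.nan, "df1": 0, "df2": 0, "pvalue": np.nan,
        "n": int(ok.sum() // 2), "monomorphic": False,
    }
    present = set(rec_codes[ok])
    if len(present) < 2:
        out["monomorphic"] = True
        return out

    M, levels = _marker_dummies(rec_codes[ok])
    GxE = M * env_wl[ok][:, None]

    if ok.all():
        def whiten(A):
            return eig2.whiten(eig2.rotate(A), vc.lam)

        yw, Xw0 = yw_full, Xw0_full
    else:
        if K2 is None:
            K2 = eig2.matrix()
        V = vc.lam * K2[np.ix_(ok, ok)] + np.eye(int(ok.sum()))
        L = np.linalg.cholesky(V)

        def whiten(A):
            return np.linalg.solve(L, A)

        yw = whiten(y[ok])
        Xw0 = whiten(X0[ok])

    Mw, GxEw = whiten(M), whiten(GxE)
    Xw_red = np.column_stack([Xw0, Mw])
    Xw_full = np.column_stack([Xw_red, GxEw])

    beta1, *_ = np.linalg.lstsq(Xw_full, yw, rcond=None)
    rss1 = float(np.sum((yw - Xw_full @ beta1) ** 2))
    beta0, *_ = np.linalg.lstsq(Xw_red, yw, rcond=None)
    rss0 = float(np.sum((yw - Xw_red @ beta0) ** 2))

    q = GxE.shape[1]
    df2 = int(ok.sum()) - Xw_full.shape[1]
    if df2 <= 0 or rss1 <= 0:
        return out
    fstat = ((rss0 - rss1) / q) / (rss1 / df2)
    pvalue = float(stats.f.sf(fstat, q, df2))

    p0 = Xw0.shape[1]
    main = dict(zip(levels, beta1[p0 : p0 + len(levels)]))
    inter = dict(zip(levels, beta1[p0 + len(levels) : p0 + 2 * len(levels)]))
    for lev, tag in ((1.0, "hvhs"), (2.0, "hshs")):
        if lev in main:
            out[f"effect_{tag}_ww"] = float(main[lev])
            out[f"effect_{tag}_wl"] = float(main[lev] + inter[lev])
    out.update(fstat=float(fstat), df1=q, df2=df2, pvalue=max(pvalue, 1e-300))
    return out


# ---------------------------------------------------------------------------
# cross-validation acceptance

def crossval(
    pop,
    phenotypes: pd.DataFrame,
    trait: str,
    model: str = "qxe",
    environment: str | None = None,
    replicates: int = 200,
    fraction: float = 0.70,
    alpha: float = 0.05,
    rate_threshold: float = 0.30,
    seed: int | None = None,
    markers: list[str] | None = None,
    kinship: pd.DataFrame | None = None,
    return_subsamples: bool = False,
):
    """Subsample cross-validation of a genome scan.

    Each replicate draws ceil(``fraction`` * n_f) lines within every family
    without replacement, reruns the scan (variance components re-estimated
    on the subsample), and records which markers reach p < ``alpha``.  A
    marker is accepted as a putative QTL when its detection rate (detected
    replicates / total replicates) is at least ``rate_threshold``.
    """
    from .genodata import compute_kinship

    if not 0 < fraction <= 1:
        raise ValueError("subsample fraction must lie in (0, 1]")
    if model == "per-se" and environment is None:
        raise ValueError("per-se cross-validation needs an environment")
    fam_sizes = pop.families.value_counts()
    if (fam_sizes < 2).any():
        raise ValueError("every family needs at least 2 lines for subsampling")
    if kinship is None:
        kinship = compute_kinship(pop)
    markers = markers if markers is not None else pop.markers

    rng = np.random.default_rng(seed)
    by_family = {f: idx.to_numpy() for f, idx in pop.genotypes.index.groupby(pop.families).items()}
    detect = pd.Series(0, index=markers, dtype=int)
    subsamples: list[list] = []
    for _ in range(replicates):
        chosen: list = []
        for f, lines in by_family.items():
            k = math.ceil(fraction * len(lines))
            chosen.extend(rng.choice(lines, size=k, replace=False))
        chosen = [l for l in pop.genotypes.index if l in set(chosen)]
        if return_subsamples:
            subsamples.append(chosen)
        sub = pop.subset_lines(chosen)
        ksub = kinship.loc[chosen, chosen]
        if model == "qxe":
            scan = scan_qxe(sub, phenotypes, trait, kinship=ksub, markers=markers)
        elif model == "per-se":
            scan = scan_per_se(
                sub, phenotypes, trait, environment, kinship=ksub, markers=markers
            )
        else:
            raise ValueError(f"unknown model {model!r}")
        hits = scan.set_index("marker")["pvalue"] < alpha
        detect.loc[hits.index[hits]] += 1

    rate = detect / replicates
    out = pd.DataFrame(
        {
            "marker": markers,
            "n_replicates": replicates,
            "n_detected": detect.to_numpy(),
            "detection_rate": rate.to_numpy(),
            "accepted": (rate >= rate_threshold).to_numpy(),
        }
    )
    out = out.merge(
        pop.linkage_map[["marker", "chromosome", "position_cm"]], on="marker", how="left"
    )
    return (out, subsamples) if return_subsamples else out


def window_peaks(
    scan: pd.DataFrame, linkage_map: pd.DataFrame | None = None, window_cm: float = 5.0
) -> pd.DataFrame:
    """Peak marker per consecutive ``window_cm`` interval.

    Chromosomes are tiled into half-open windows [0, w), [w, 2w), ... from
    position 0; within each window the marker with the smallest p-value is
    the peak, ties broken by lower cM then lexical marker id.
    """
    df = scan.copy()
    if "position_cm" not in df.columns:
        if linkage_map is None:
            raise ValueError("scan lacks map positions and no map was given")
        df = df.merge(linkage_map[["marker", "chromosome", "position_cm"]], on="marker")
    df = df.dropna(subset=["pvalue"])
    df["window"] = np.floor(df["position_cm"] / window_cm).astype(int)
    df = df.sort_values(
        ["chromosome", "window", "pvalue", "position_cm", "marker"], kind="stable"
    )
    peaks = df.groupby(["chromosome", "window"], as_index=False).first()
    peaks["window_start_cm"] = peaks["window"] * window_cm
    keep = ["chromosome", "window_start_cm", "marker", "position_cm", "pvalue"]
    extra = [c for c in ("detection_rate", "accepted", "effect_hshs") if c in peaks.columns]
    return peaks[keep + extra].reset_index(drop=True)


def reaction_norms(
    pop, phenotypes: pd.DataFrame, marker: str, trait: str, family: str | None = None
) -> pd.DataFrame:
    """Least-squares means of the three genotype classes per environment,
    adjusted for family (equal family weights).

    Restricting to one ``family`` reproduces the family-wise dissection of a
    QxE locus.  Classes empty in the data get missing means.
    """
    import statsmodels.formula.api as smf

    if marker not in pop.genotypes.columns:
        raise ValueError(f"marker {marker!r} not in population")
    sub = phenotypes[phenotypes["trait"] == trait].dropna(subset=["value"]).copy()
    sub = sub[sub["line"].isin(pop.genotypes.index)]
    sub["genotype"] = pop.genotypes.loc[sub["line"], marker].to_numpy()
    sub["family"] = pop.families.loc[sub["line"]].to_numpy()
    sub = sub.dropna(subset=["genotype"])
    if family is not None:
        sub = sub[sub["family"] == family]
    sub["genotype"] = sub["genotype"].astype(int).astype(str)

    multi_family = sub["family"].nunique() > 1
    formula = "value ~ C(genotype) * C(environment)"
    if multi_family:
        formula += " + C(family)"
    fit = smf.ols(formula, data=sub).fit()

    fams = sorted(sub["family"].unique())
    present = set(sub["genotype"])
    rows = []
    for geno in ("0", "1", "2"):
        for env in sorted(sub["environment"].unique()):
            if geno not in present:
                rows.append({"genotype": int(geno), "environment": env,
                             "lsmean": np.nan, "n": 0})
                continue
            cells = sub[(sub["genotype"] == geno) & (sub["environment"] == env)]
            if cells.empty:
                rows.append({"genotype": int(geno), "environment": env,
                             "lsmean": np.nan, "n": 0})
                continue
            grid = pd.DataFrame(
                {"genotype": geno, "environment": env, "family": fams}
            )
            rows.append(
                {
                    "genotype": int(geno),
                    "environment": env,
                    "lsmean": float(fit.predict(grid).mean()),
                    "n": len(cells),
                }
            )
    return pd.DataFrame(rows)
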