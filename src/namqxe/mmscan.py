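"""Kinship mixed-linear-model engine and the per-environment genome scan.

Model for a trait per se, per environment:

    y = mu + F_family + G_marker + u + eps,   u ~ N(0, sigma2_g K),
                                              eps ~ N(0, sigma2_e I)

with the marker fitted as a 3-level genotype class (Hv/Hv reference,
Hv/Hs, Hs/Hs) and the family as fixed dummies.  Variance components are
estimated once per trait/environment by REML on the no-marker null model
(EMMA-style: one eigendecomposition of K, then 1-D optimisation of the
profiled restricted likelihood over lambda = sigma2_g / sigma2_e) and
reused across markers (P3D); an exact per-marker refit is available.

Marker tests are generalized-least-squares F-tests of the joint 2-df
genotype-class contrast under V = sigma2_g K + sigma2_e I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "fit_null_reml",
    "reml_objective",
    "test_marker",
    "scan_per_se",
    "design_matrices",
    "KinshipEigen",
]

LAMBDA_LOG10_BOUNDS = (-5.0, 5.0)


@dataclass(frozen=True)
class VarianceComponents:
    """REML estimates: polygenic variance, residual variance, their ratio
    lambda, and the restricted log-likelihood at the optimum."""

    sigma2_g: float
    sigma2_e: float
    lam: float
    reml_loglik: float


class KinshipEigen:
    """Eigendecomposition of a kinship matrix, cached for reuse across
    markers and for whitening under any lambda."""

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        s, U = np.linalg.eigh((K + K.T) / 2.0)
        if s.min() < -1e-6 * max(1.0, s.max()):
            raise ValueError(f"kinship matrix is not PSD (min eigenvalue {s.min():.3g})")
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.n = K.shape[0]

    @classmethod
    def from_eigen(cls, s: np.ndarray, U: np.ndarray) -> "KinshipEigen":
        obj = cls.__new__(cls)
        obj.s = np.clip(np.asarray(s, float), 0.0, None)
        obj.U = np.asarray(U, float)
        obj.n = obj.U.shape[0]
        return obj

    def matrix(self) -> np.ndarray:
        return self.U @ (self.s[:, None] * self.U.T)

    def rotate(self, A: np.ndarray) -> np.ndarray:
        return self.U.T @ A

    def whiten(self, A_rot: np.ndarray, lam: float) -> np.ndarray:
        w = lam * self.s + 1.0
        return A_rot / np.sqrt(w)[:, None] if A_rot.ndim == 2 else A_rot / np.sqrt(w)


def reml_objective(lam: float, y_rot: np.ndarray, X_rot: np.ndarray, s: np.ndarray) -> float:
    """Profiled restricted log-likelihood at variance ratio ``lam`` (up to a
    lambda-free constant), after rotation into the kinship eigenbasis."""
    n, p = X_rot.shape
    w = lam * s + 1.0
    sw = np.sqrt(w)
    Xw = X_rot / sw[:, None]
    yw = y_rot / sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
    return -0.5 * (dof * np.log(2 * np.pi * sigma2) + dof + np.sum(np.log(w)) + logdet_xx)


def fit_null_reml(
    y: np.ndarray,
    X0: np.ndarray,
    K: np.ndarray | KinshipEigen,
    tol: float = 1e-8,
    n_grid: int = 64,
) -> VarianceComponents:
    """REML variance components for y = X0 b + u + e, u ~ N(0, sigma2_g K).

    One eigendecomposition of K, then the profiled restricted likelihood is
    maximised over lambda on a log10 grid spanning [1e-5, 1e5] followed by
    bounded scalar refinement around the best grid cell.  lambda = 0 (pure
    residual) is always a candidate.
    """
    y = np.asarray(y, dtype=float).ravel()
    X0 = np.asarray(X0, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    if y.shape[0] != X0.shape[0]:
        raise ValueError("response and design dimensions disagree")
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen(np.asarray(K))
    if eig.n != y.shape[0]:
        raise ValueError("kinship dimension does not match response")

    y_rot = eig.rotate(y)
    X_rot = eig.rotate(X0)
    s = eig.s

    lo, hi = LAMBDA_LOG10_BOUNDS
    grid = np.concatenate([[-np.inf], np.linspace(lo, hi, n_grid)])  # -inf => lam = 0
    lams = np.where(np.isfinite(grid), 10.0**grid, 0.0)
    objs = np.array([reml_objective(l, y_rot, X_rot, s) for l in lams])
    best = int(np.argmax(objs))

    lam_hat, obj_hat = lams[best], objs[best]
    if best > 0:  # refine in log10 space around the best interior point
        a = grid[max(best - 1, 1)]
        b = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -reml_objective(10.0**t, y_rot, X_rot, s),
            bounds=(a, b),
            method="bounded",
            options={"xatol": tol},
        )
        if -res.fun > obj_hat:
            lam_hat, obj_hat = 10.0**res.x, -res.fun

    # plug-in variance estimates at the optimum
    w = lam_hat * s + 1.0
    sw = np.sqrt(w)
    Xw, yw = X_rot / sw[:, None], y_rot / sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma2_e = rss / (len(y) - X0.shape[1])
    return VarianceComponents(
        sigma2_g=lam_hat * sigma2_e, sigma2_e=sigma2_e, lam=lam_hat, reml_loglik=obj_hat
    )


# ---------------------------------------------------------------------------
# marker test

def _marker_dummies(codes: np.ndarray) -> tuple[np.ndarray, list[float]]:
    """Dummy columns for the genotype classes present, reference Hv/Hv
    (code 0; or the lowest present code if 0 is absent)."""
    present = sorted(set(codes))
    ref = 0.0 if 0.0 in present else present[0]
    levels = [c for c in present if c != ref]
    cols = np.column_stack([(codes == c).astype(float) for c in levels]) if levels else np.empty((len(codes), 0))
    return cols, levels


def test_marker(
    y: np.ndarray,
    X0: np.ndarray,
    codes: np.ndarray,
    K: np.ndarray | KinshipEigen,
    vc: VarianceComponents,
    coding: str = "class",
    Kmat: np.ndarray | None = None,
) -> dict:
    """GLS F-test of one marker under V = sigma2_g K + sigma2_e I.

    Lines missing at the marker are dropped (the whitening is then redone on
    the subset covariance).  Effects are reported relative to the Hv/Hv
    class; ``coding="additive"`` fits the 0/1/2 dosage as a single slope
    instead of class dummies.
    """
    y = np.asarray(y, dtype=float).ravel()
    X0 = np.asarray(X0, dtype=float)
    codes = np.asarray(codes, dtype=float).ravel()
    ok = ~np.isnan(codes) & ~np.isnan(y)
    n_used = int(ok.sum())
    out = {
        "effect_hvhs": np.nan,
        "effect_hshs": np.nan,
        "fstat": np.nan,
        "df1": 0,
        "df2": 0,
        "pvalue": np.nan,
        "n": n_used,
        "monomorphic": False,
    }

    codes_u = codes[ok]
    if len(set(codes_u)) < 2:
        out["monomorphic"] = True
        return out

    if ok.all() and isinstance(K, KinshipEigen):
        yw = K.whiten(K.rotate(y), vc.lam)
        Xw0 = K.whiten(K.rotate(X0), vc.lam)

        def whiten(A):
            return K.whiten(K.rotate(A), vc.lam)
    else:
        if Kmat is None:
            Kmat = K.matrix() if isinstance(K, KinshipEigen) else np.asarray(K, float)
        V = vc.lam * Kmat[np.ix_(ok, ok)] + np.eye(n_used)
        L = np.linalg.cholesky(V)

        def whiten(A):
            return np.linalg.solve(L, A)

        yw = whiten(y[ok])
        Xw0 = whiten(X0[ok])

    if coding == "additive":
        M = codes_u[:, None]
        levels = ["dose"]
    else:
        M, levels = _marker_dummies(codes_u)
    Mw = whiten(M) if M.size else M

    Xw_full = np.column_stack([Xw0, Mw])
    beta1, _, rank1, _ = np.linalg.lstsq(Xw_full, yw, rcond=None)
    rss1 = float(np.sum((yw - Xw_full @ beta1) ** 2))
    beta0, *_ = np.linalg.lstsq(Xw0, yw, rcond=None)
    rss0 = float(np.sum((yw - Xw0 @ beta0) ** 2))

    q = M.shape[1]
    p_full = Xw_full.shape[1]
    df2 = n_used - p_full
    if df2 <= 0 or rss1 <= 0:
        return out
    fstat = ((rss0 - rss1) / q) / (rss1 / df2)
    pvalue = float(stats.f.sf(fstat, q, df2))

    eff = dict(zip(levels, beta1[X0.shape[1] :]))
    if coding == "additive":
        out["effect_hshs"] = 2.0 * float(eff["dose"])
        out["effect_hvhs"] = float(eff["dose"])
    else:
        out["effect_hvhs"] = float(eff.get(1.0, np.nan))
        out["effect_hshs"] = float(eff.get(2.0, np.nan))
    out.update(fstat=float(fstat), df1=q, df2=df2, pvalue=max(pvalue, 1e-300))
    return out


# ---------------------------------------------------------------------------
# genome scan

def design_matrices(families: pd.Series) -> np.ndarray:
    """Intercept plus family dummy columns (first family as reference)."""
    fam = pd.Categorical(families)
    dummies = pd.get_dummies(fam, drop_first=True).to_numpy(dtype=float)
    return np.column_stack([np.ones(len(families)), dummies])


def _align_response(pop, phenotypes: pd.DataFrame, trait: str, environment: str):
    sub = phenotypes[
        (phenotypes["trait"] == trait) & (phenotypes["environment"] == environment)
    ]
    sub = sub.dropna(subset=["value"]).drop_duplicates(subset="line")
    lines = [l for l in pop.genotypes.index if l in set(sub["line"])]
    if not lines:
        raise ValueError(f"no phenotyped lines for {trait!r} in {environment!r}")
    y = sub.set_index("line").loc[lines, "value"].to_numpy(float)
    return lines, y


def scan_per_se(
    pop,
    phenotypes: pd.DataFrame,
    trait: str,
    environment: str,
    kinship: pd.DataFrame | None = None,
    markers: list[str] | None = None,
    coding: str = "class",
    p3d: bool = True,
) -> pd.DataFrame:
    """Genome scan for a trait per se in one environment.

    ``phenotypes`` are per-line means (long format).  Variance components
    are estimated once on the no-marker null model and reused for every
    marker (P3D); ``p3d=False`` refits lambda per marker with the marker in
    the fixed design.  Returns one row per marker with the class effects
    relative to Hv/Hv, the joint F statistic and p-value.
    """
    from .genodata import compute_kinship

    lines, y = _align_response(pop, phenotypes, trait, environment)
    sub = pop.subset_lines(lines)
    if kinship is None:
        kinship = compute_kinship(sub)
    Kmat = kinship.loc[lines, lines].to_numpy(float)
    eig = KinshipEigen(Kmat)
    X0 = design_matrices(sub.families)
    vc = fit_null_reml(y, X0, eig)

    markers = markers if markers is not None else sub.markers
    has_missing = sub.genotypes[markers].isna().to_numpy().any()
    Kcache = Kmat if has_missing else None
    rows = []
    for m in markers:
        codes = sub.genotypes[m].to_numpy(float)
        if not p3d:
            okm = ~np.isnan(codes)
            Mm, _ = _marker_dummies(codes[okm])
            if Mm.size and okm.all():
                Xm = np.column_stack([X0, Mm])
                vc_m = fit_null_reml(y, Xm, eig)
            else:
                vc_m = vc
            res = test_marker(y, X0, codes, eig, vc_m, coding=coding, Kmat=Kcache)
        else:
            res = test_marker(y, X0, codes, eig, vc, coding=coding, Kmat=Kcache)
        res["marker"] = m
        rows.append(res)
    out = pd.DataFrame(rows)
    out["trait"] = trait
    out["environment"] = environment
    out["model"] = "per-se"
    cols = [
        "marker", "trait", "environment", "model",
        "effect_hvhs", "effect_hshs", "fstat", "df1", "df2",
        "pvalue", "n", "monomorphic",
    ]
    return out[cols].merge(
        pop.linkage_map[["marker", "chromosome", "position_cm"]], on="marker", how="left"
    )
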