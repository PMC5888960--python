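"""Synthetic NAM population and phenotype simulator.

Emulates the structure of a barley-style nested association mapping panel:
25 interspecific families of BC1S3 lines sharing one recurrent (cultivated)
parent, each family contributed by a different wild donor.  Genotypes are
produced by gamete-level simulation of the crossing scheme (backcrosses and
selfings) with Haldane recombination along a genetic map, so genotype-class
frequencies and linkage decay follow from the scheme rather than being
painted on.  Phenotypes are generated from an explicit architecture:

    value = mu + F_family + sum(locus effects, incl. WL-only QxE terms)
            + E_WL * 1[WL] + polygenic (covariance prop. to kinship)
            + residual (per-environment SD),

optionally scaled per year so the cross-year adjustment has work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import BreedingScheme, Population, validate_linkage_map

__all__ = [
    "generate_map",
    "expected_genotype_freqs",
    "simulate_family",
    "simulate_population",
    "QtlEffect",
    "ArchitectureSpec",
    "simulate_phenotypes",
    "inject_missing",
]


# ---------------------------------------------------------------------------
# genetic map

def generate_map(
    n_chromosomes: int,
    chrom_length_cm: float,
    n_markers: int,
    seed: int | None = None,
    spacing: str = "even",
) -> pd.DataFrame:
    """Lay out ``n_markers`` over ``n_chromosomes`` chromosomes.

    Markers are split as evenly as possible across chromosomes.  With
    ``spacing="even"`` positions are equidistant from 0 to the chromosome
    length; ``spacing="uniform"`` draws sorted uniform positions (needs a
    seed for reproducibility).
    """
    if n_chromosomes <= 0 or n_markers <= 0 or chrom_length_cm <= 0:
        raise ValueError("chromosome count, marker count and length must be positive")
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_markers, n_chromosomes)
    rows = []
    for c in range(1, n_chromosomes + 1):
        k = base + (1 if c <= extra else 0)
        if spacing == "even":
            pos = np.linspace(0.0, chrom_length_cm, k) if k > 1 else np.array([chrom_length_cm / 2])
        elif spacing == "uniform":
            pos = np.sort(rng.uniform(0.0, chrom_length_cm, size=k))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        for i, p in enumerate(pos, start=1):
            rows.append((f"M{c}_{i}", c, float(p)))
    out = pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"])
    return validate_linkage_map(out)


# ---------------------------------------------------------------------------
# crossing-scheme expectations

def expected_genotype_freqs(scheme: BreedingScheme) -> tuple[float, float, float]:
    """Exact single-locus genotype frequencies implied by the crossing scheme.

    Markov chain on (f_HvHv, f_HvHs, f_HsHs), starting from the fully
    heterozygous F1.  A backcross to the recurrent parent sends every
    heterozygote half to Hv/Hv and half to Hv/Hs, and every donor homozygote
    to Hv/Hs.  A selfing halves heterozygosity, splitting the loss equally
    between the two homozygote classes.

    For BC1S3 this gives (0.71875, 0.0625, 0.21875).
    """
    p = np.array([0.0, 1.0, 0.0])  # F1
    backcross = np.array(
        [
            [1.0, 0.5, 0.0],
            [0.0, 0.5, 1.0],
            [0.0, 0.0, 0.0],
        ]
    )
    selfing = np.array(
        [
            [1.0, 0.25, 0.0],
            [0.0, 0.50, 0.0],
            [0.0, 0.25, 1.0],
        ]
    )
    for _ in range(scheme.backcrosses):
        p = backcross @ p
    for _ in range(scheme.selfings):
        p = selfing @ p
    return float(p[0]), float(p[1]), float(p[2])


# ---------------------------------------------------------------------------
# gamete-level simulation

def _recomb_fractions(linkage_map: pd.DataFrame) -> np.ndarray:
    """Haldane recombination fraction between each marker and the previous
    one; 0.5 at the first marker of each chromosome (free start)."""
    pos = linkage_map["position_cm"].to_numpy(dtype=float)
    chrom = linkage_map["chromosome"].to_numpy()
    d = np.diff(pos, prepend=pos[:1])
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    new_chrom = np.ones_like(r, dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    r[new_chrom] = 0.5
    r[0] = 0.5
    return r


def _gametes(h1: np.ndarray, h2: np.ndarray, rec: np.ndarray, rng) -> np.ndarray:
    """One gamete per row individual, no crossover interference."""
    switch = rng.random(h1.shape) < rec[None, :]
    take_h2 = np.bitwise_xor.accumulate(switch, axis=1)
    return np.where(take_h2, h2, h1)


def simulate_family(
    donor: str,
    n_lines: int,
    scheme: BreedingScheme,
    linkage_map: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
    donor_haplotype: np.ndarray | None = None,
    family_label=None,
) -> Population:
    """Simulate one family of lines from (recurrent x ``donor``) by the
    given crossing scheme.

    Each line descends from its own F1 gamete lineage (single-seed descent
    through the selfings), so genotype frequencies converge to
    :func:`expected_genotype_freqs` and linkage follows the Haldane map.
    ``donor_haplotype`` (0/1 per marker, 1 = donor allele present) lets the
    donor be uninformative at some markers; default all ones.
    """
    linkage_map = validate_linkage_map(linkage_map)
    m = len(linkage_map)
    if m == 0:
        raise ValueError("linkage map is empty")
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if donor_haplotype is None:
        donor_haplotype = np.ones(m, dtype=np.uint8)
    donor_haplotype = np.asarray(donor_haplotype, dtype=np.uint8)
    rec = _recomb_fractions(linkage_map)

    h1 = np.zeros((n_lines, m), dtype=np.uint8)  # recurrent haplotype
    h2 = np.tile(donor_haplotype, (n_lines, 1))  # donor haplotype (F1)
    for _ in range(scheme.backcrosses):
        gam = _gametes(h1, h2, rec, rng)
        h1, h2 = np.zeros_like(gam), gam
    for _ in range(scheme.selfings):
        g1 = _gametes(h1, h2, rec, rng)
        g2 = _gametes(h1, h2, rec, rng)
        h1, h2 = g1, g2

    codes = (h1 + h2).astype(float)
    label = donor if family_label is None else family_label
    lines = [f"{label}_{i + 1:04d}" for i in range(n_lines)]
    geno = pd.DataFrame(codes, index=lines, columns=list(linkage_map["marker"]))
    fam = pd.Series([label] * n_lines, index=lines, name="family")
    return Population(genotypes=geno, families=fam, linkage_map=linkage_map)


def simulate_population(
    linkage_map: pd.DataFrame,
    n_families: int = 25,
    n_per_family: int = 57,
    scheme: BreedingScheme | None = None,
    donor_carrier_prob: float = 0.5,
    missing_rate: float = 0.02,
    seed: int | None = None,
) -> Population:
    """Simulate a full NAM panel: ``n_families`` donors crossed to one
    recurrent parent, ``n_per_family`` lines each.

    Donor alleles are family-private: each donor carries the non-recurrent
    allele at a given marker independently with ``donor_carrier_prob``, so a
    marker segregates only in the families whose donor carries it —
    mirroring a NAM design where rare alleles are family-specific.  The
    defaults (25 x 57 = 1425 lines, BC1S3) match the panel the pipeline is
    designed around.  Missing genotypes are injected at ``missing_rate``.

    One master seed; per-family streams are spawned deterministically.
    """
    scheme = scheme or BreedingScheme()
    linkage_map = validate_linkage_map(linkage_map)
    master = np.random.default_rng(seed)
    family_rngs = master.spawn(n_families + 1)
    parts = []
    for f in range(1, n_families + 1):
        rng = family_rngs[f - 1]
        hap = (rng.random(len(linkage_map)) < donor_carrier_prob).astype(np.uint8)
        parts.append(
            simulate_family(
                donor=f"F{f:02d}",
                n_lines=n_per_family,
                scheme=scheme,
                linkage_map=linkage_map,
                seed=rng,
                donor_haplotype=hap,
            )
        )
    pop = Population(
        genotypes=pd.concat([p.genotypes for p in parts]),
        families=pd.concat([p.families for p in parts]),
        linkage_map=linkage_map,
    )
    if missing_rate > 0:
        pop = inject_missing(pop, missing_rate, rng=family_rngs[-1])
    return pop


def inject_missing(
    pop: Population, rate: float, seed: int | None = None, rng=None
) -> Population:
    """Set a random ``rate`` fraction of genotype cells to missing (NaN)."""
    if not 0 <= rate < 1:
        raise ValueError("missing rate must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    vals = pop.genotypes.to_numpy(dtype=float).copy()
    mask = rng.random(vals.shape) < rate
    vals[mask] = np.nan
    geno = pd.DataFrame(vals, index=pop.genotypes.index, columns=pop.genotypes.columns)
    return Population(genotypes=geno, families=pop.families.copy(), linkage_map=pop.linkage_map.copy())


# ---------------------------------------------------------------------------
# phenotype architecture

@dataclass(frozen=True)
class QtlEffect:
    """One causal locus.

    ``effect`` is the Hs/Hs minus Hv/Hv difference for the trait per se
    (heterozygotes get half, or the full effect if ``dominant``).
    ``qxe_wl`` is an additional Hs/Hs-vs-Hv/Hv difference expressed only
    under water-limited (WL) conditions — the QxE term.
    """

    marker: str
    effect: float = 0.0
    dominant: bool = False
    qxe_wl: float = 0.0

    def genetic_value(self, codes: np.ndarray, wl: bool) -> np.ndarray:
        total = self.effect + (self.qxe_wl if wl else 0.0)
        if self.dominant:
            dose = np.where(np.nan_to_num(codes) > 0, 1.0, 0.0)
        else:
            dose = np.nan_to_num(codes) / 2.0
        return dose * total


@dataclass
class ArchitectureSpec:
    """Generative architecture for one trait.

    ``residual_sd`` maps environment -> residual SD; WL is typically given a
    larger SD than WW, reproducing the inflated coefficient of variation
    observed under water limitation.  ``heritability`` is the fraction of
    non-QTL variance attributed to the polygenic (kinship-structured) term.
    ``year_scale`` multiplies all records of a year, emulating between-season
    level shifts that the cross-year adjustment is meant to undo.
    """

    trait: str
    mean: float = 0.0
    family_effects: dict = field(default_factory=dict)
    loci: list[QtlEffect] = field(default_factory=list)
    heritability: float = 0.0
    env_effect_wl: float = 0.0
    residual_sd: dict = field(default_factory=lambda: {"WW": 1.0, "WL": 1.0})
    year_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.heritability <= 1:
            raise ValueError("heritability must lie in [0, 1]")
        if any(sd <= 0 for sd in self.residual_sd.values()):
            raise ValueError("residual SDs must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        """Load an architecture from a plain key-value (YAML) file; the
        ``loci`` entry is a list of mappings with keys marker, effect,
        dominant, qxe_wl."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        loci = [QtlEffect(**d) for d in raw.pop("loci", [])]
        raw["year_scale"] = {int(k): float(v) for k, v in raw.get("year_scale", {}).items()}
        return cls(loci=loci, **raw)

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _polygenic_draw(kinship: np.ndarray, sigma2_g: float, rng) -> np.ndarray:
    if sigma2_g <= 0:
        return np.zeros(kinship.shape[0])
    k = kinship + 1e-8 * np.eye(kinship.shape[0])
    chol = np.linalg.cholesky(k)
    return np.sqrt(sigma2_g) * (chol @ rng.standard_normal(kinship.shape[0]))


def simulate_phenotypes(
    pop: Population,
    spec: ArchitectureSpec,
    environments: tuple[str, ...] = ("WW", "WL"),
    years: int = 2,
    kinship: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a long-format phenotype table from the generative model.

    Returns records (line, family, year, environment, trait, value).  The
    polygenic term is drawn once per line (shared across environments and
    years) with covariance ``sigma2_g * K`` where ``sigma2_g`` is set so
    that sigma2_g / (sigma2_g + mean residual variance) equals the
    specified heritability.  Residual noise is independent per record with
    the per-environment SD.
    """
    for locus in spec.loci:
        if locus.marker not in pop.genotypes.columns:
            raise ValueError(f"causal marker {locus.marker!r} not in population")
    for env in environments:
        if env not in spec.residual_sd:
            raise ValueError(f"no residual SD specified for environment {env!r}")
    rng = np.random.default_rng(seed)
    n = pop.n_lines

    fam_eff = pop.families.map(lambda f: spec.family_effects.get(f, 0.0)).to_numpy(float)
    mean_res_var = float(np.mean([sd**2 for sd in spec.residual_sd.values()]))
    if spec.heritability > 0:
        if kinship is None:
            raise ValueError("heritability > 0 requires a kinship matrix")
        h2 = spec.heritability
        sigma2_g = h2 / (1.0 - h2) * mean_res_var if h2 < 1 else mean_res_var * 1e6
        kmat = kinship.loc[pop.genotypes.index, pop.genotypes.index].to_numpy(float)
        u = _polygenic_draw(kmat, sigma2_g, rng)
    else:
        u = np.zeros(n)

    records = []
    for year in range(1, years + 1):
        scale = float(spec.year_scale.get(year, 1.0))
        for env in environments:
            wl = env == "WL"
            g = np.zeros(n)
            for locus in spec.loci:
                codes = pop.genotypes[locus.marker].to_numpy(float)
                g += locus.genetic_value(codes, wl)
            eps = rng.normal(0.0, spec.residual_sd[env], size=n)
            value = spec.mean + fam_eff + g + (spec.env_effect_wl if wl else 0.0) + u + eps
            value = value * scale
            records.append(
                pd.DataFrame(
                    {
                        "line": pop.genotypes.index,
                        "family": pop.families.to_numpy(),
                        "year": year,
                        "environment": env,
                        "trait": spec.trait,
                        "value": value,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
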