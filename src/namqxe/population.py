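"""Core in-memory containers shared across the pipeline.

A multi-parent NAM panel is represented by :class:`Population`: a lines x
markers genotype matrix coded 0 (recurrent-parent homozygote, Hv/Hv),
1 (heterozygote, Hv/Hs), 2 (donor homozygote, Hs/Hs) with NaN for missing;
a per-line family (wild-donor) label; and a genetic map in centimorgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAP_COLUMNS = ("marker", "chromosome", "position_cm")

#: Valid genotype codes (missing is NaN).
GENOTYPE_CODES = (0.0, 1.0, 2.0)


def validate_linkage_map(linkage_map: pd.DataFrame) -> pd.DataFrame:
    """Check a genetic map for the invariants the pipeline relies on.

    Markers must be unique, chromosomes integer-valued, positions
    non-negative and non-decreasing within each chromosome.  Returns the
    map sorted by (chromosome, position).
    """
    missing = set(MAP_COLUMNS) - set(linkage_map.columns)
    if missing:
        raise ValueError(f"linkage map lacks columns: {sorted(missing)}")
    if linkage_map["marker"].duplicated().any():
        dupes = linkage_map.loc[linkage_map["marker"].duplicated(), "marker"]
        raise ValueError(f"duplicate marker identifiers: {list(dupes[:5])}")
    if (linkage_map["position_cm"] < 0).any():
        raise ValueError("map positions must be non-negative (cM)")
    out = linkage_map.sort_values(["chromosome", "position_cm"], kind="stable")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class BreedingScheme:
    """Number of backcrosses to the recurrent parent and of selfing
    generations applied to the F1 of a (recurrent x donor) cross.

    The default BC=1, S=3 describes BC1S3 lines: one backcross followed by
    three rounds of single-seed-descent selfing.
    """

    backcrosses: int = 1
    selfings: int = 3

    def __post_init__(self) -> None:
        if self.backcrosses < 0 or self.selfings < 0:
            raise ValueError("backcross/selfing counts must be >= 0")


@dataclass
class Population:
    """Genotypes, family labels and genetic map for a set of inbred-ish lines.

    Attributes
    ----------
    genotypes : pd.DataFrame
        lines x markers; float entries in {0, 1, 2} or NaN.
    families : pd.Series
        Family (donor) label per line, aligned to ``genotypes.index``.
    linkage_map : pd.DataFrame
        Columns ``marker``, ``chromosome``, ``position_cm``; one row per
        genotype column, in map order.
    """

    genotypes: pd.DataFrame
    families: pd.Series
    linkage_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.linkage_map = validate_linkage_map(self.linkage_map)
        if not self.families.index.equals(self.genotypes.index):
            self.families = self.families.reindex(self.genotypes.index)
        if self.families.isna().any():
            bad = self.families.index[self.families.isna()]
            raise ValueError(f"lines without a family label: {list(bad[:5])}")
        markers = list(self.linkage_map["marker"])
        if set(markers) != set(self.genotypes.columns):
            raise ValueError("genotype columns and map markers disagree")
        # keep matrix in map order
        self.genotypes = self.genotypes[markers]
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, GENOTYPE_CODES)
        if not ok.all():
            rows = self.genotypes.index[np.nonzero(~ok.all(axis=1))[0]]
            raise ValueError(
                f"invalid genotype codes (expected 0/1/2/NA) in lines {list(rows[:5])}"
            )

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def markers(self) -> list[str]:
        return list(self.genotypes.columns)

    def subset_lines(self, lines) -> "Population":
        """Restrict to the given line identifiers (order preserved)."""
        return Population(
            genotypes=self.genotypes.loc[lines].copy(),
            families=self.families.loc[lines].copy(),
            linkage_map=self.linkage_map.copy(),
        )

    def equals(self, other: "Population") -> bool:
        return (
            self.genotypes.equals(other.genotypes)
            and self.families.equals(other.families)
            and self.linkage_map.equals(other.linkage_map)
        )
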