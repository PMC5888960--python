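import numpy as np
import pandas as pd
import pytest

import namqxe as nq


@pytest.fixture(scope="session")
def small_map() -> pd.DataFrame:
    return nq.generate_map(2, 100, 30)


@pytest.fixture(scope="session")
def nam_pop(small_map):
    """Medium NAM panel: 6 families x 40 BC1S3 lines, 30 markers, no
    missing calls (tests that need missingness inject it themselves)."""
    return nq.simulate_population(
        small_map, n_families=6, n_per_family=40, missing_rate=0.0, seed=42
    )


@pytest.fixture(scope="session")
def nam_kinship(nam_pop):
    return nq.compute_kinship(nam_pop)


@pytest.fixture(scope="session")
def qxe_world(nam_pop, nam_kinship):
    """Phenotypes with a WL-only QTL at a known marker, plus polygenic and
    family structure."""
    marker = nam_pop.markers[12]
    arch = nq.ArchitectureSpec(
        trait="GN",
        mean=100.0,
        family_effects={f: e for f, e in zip(sorted(set(nam_pop.families)), np.linspace(-4, 4, 6))},
        loci=[nq.QtlEffect(marker, effect=0.0, qxe_wl=-8.0)],
        heritability=0.3,
        env_effect_wl=-20.0,
        residual_sd={"WW": 4.0, "WL": 4.0},
    )
    pheno = nq.simulate_phenotypes(nam_pop, arch, kinship=nam_kinship, seed=7)
    means = nq.line_means(pheno)
    return {"marker": marker, "arch": arch, "pheno": pheno, "means": means}


@pytest.fixture()
def toy_phenotypes() -> pd.DataFrame:
    """Two lines, two years, one environment; year-1 mean 50, year-2 mean
    60, both-year mean 55 for trait X."""
    rows = []
    for year, vals in ((1, [40.0, 60.0]), (2, [50.0, 70.0])):
        for line, v in zip(["L1", "L2"], vals):
            rows.append(("X", line, "FAM", year, "WW", v))
    return pd.DataFrame(
        rows, columns=["trait", "line", "family", "year", "environment", "value"]
    )[["line", "family", "year", "environment", "trait", "value"]]
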