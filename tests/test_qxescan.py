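"""Interaction scan, cross-validation acceptance, window peaks and
reaction norms."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import namqxe as nq
from namqxe.qxescan import crossval, reaction_norms, scan_qxe, window_peaks


class TestScanQxe:
    def test_single_environment_rejected(self, nam_pop, qxe_world):
        means = qxe_world["means"]
        ww_only = means[means["environment"] == "WW"]
        with pytest.raises(ValueError, match="scan_per_se"):
            scan_qxe(nam_pop, ww_only, "GN")

    def test_detects_wl_only_effect(self, nam_pop, nam_kinship, qxe_world):
        scan = scan_qxe(nam_pop, qxe_world["means"], "GN", kinship=nam_kinship)
        assert scan.loc[scan["pvalue"].idxmin(), "marker"] == qxe_world["marker"]

    def test_environment_swap_symmetry(self, nam_pop, nam_kinship, qxe_world):
        """Relabelling WW <-> WL leaves the interaction p unchanged and
        swaps the environment-specific effects."""
        means = qxe_world["means"]
        swapped = means.copy()
        swapped["environment"] = swapped["environment"].map({"WW": "WL", "WL": "WW"})
        mk = [qxe_world["marker"], nam_pop.markers[0]]
        a = scan_qxe(nam_pop, means, "GN", kinship=nam_kinship, markers=mk)
        b = scan_qxe(nam_pop, swapped, "GN", kinship=nam_kinship, markers=mk)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], rtol=1e-6)
        np.testing.assert_allclose(a["effect_hshs_ww"], b["effect_hshs_wl"], rtol=1e-5)
        np.testing.assert_allclose(a["effect_hshs_wl"], b["effect_hshs_ww"], rtol=1e-5)

    def test_equal_effect_both_envs_is_null(self, small_map):
        """A marker with the same effect in WW and WL has no interaction:
        p-values over replicate traits are uniform."""
        pop = nq.simulate_population(small_map, n_families=5, n_per_family=60,
                                     missing_rate=0.0, seed=50)
        K = nq.compute_kinship(pop)
        marker = pop.markers[8]
        pvals = []
        for seed in range(51, 71):
            arch = nq.ArchitectureSpec(
                trait="T", mean=50.0, loci=[nq.QtlEffect(marker, effect=5.0, qxe_wl=0.0)],
                heritability=0.2, env_effect_wl=-10.0, residual_sd={"WW": 2.0, "WL": 2.0},
            )
            means = nq.line_means(nq.simulate_phenotypes(pop, arch, kinship=K, seed=seed))
            scan = scan_qxe(pop, means, "T", kinship=K, markers=[marker])
            pvals.append(float(scan["pvalue"].iloc[0]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCrossval:
    def test_forced_detection(self, nam_pop, nam_kinship, qxe_world):
        """A marker with an overwhelming effect is detected in every
        replicate and accepted."""
        pop = nam_pop
        marker = qxe_world["marker"]
        arch = nq.ArchitectureSpec(
            trait="BIG", mean=100.0, loci=[nq.QtlEffect(marker, effect=0.0, qxe_wl=-50.0)],
            residual_sd={"WW": 1.0, "WL": 1.0},
        )
        means = nq.line_means(nq.simulate_phenotypes(pop, arch, seed=60))
        prof = crossval(pop, means, "BIG", model="qxe", replicates=10, seed=61,
                        markers=[marker], kinship=nam_kinship)
        assert prof["detection_rate"].iloc[0] == 1.0
        assert bool(prof["accepted"].iloc[0])

    def test_determinism(self, nam_pop, nam_kinship, qxe_world):
        kw = dict(model="qxe", replicates=8, seed=62, kinship=nam_kinship,
                  markers=[qxe_world["marker"], nam_pop.markers[0]])
        a = crossval(nam_pop, qxe_world["means"], "GN", **kw)
        b = crossval(nam_pop, qxe_world["means"], "GN", **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_family_stratification(self, nam_pop, nam_kinship, qxe_world):
        """Each replicate draws ceil(0.7 n_f) lines within every family."""
        _, subs = crossval(
            nam_pop, qxe_world["means"], "GN", model="qxe", replicates=4,
            fraction=0.70, seed=63, markers=[qxe_world["marker"]],
            kinship=nam_kinship, return_subsamples=True,
        )
        fam_sizes = nam_pop.families.value_counts()
        for chosen in subs:
            counts = nam_pop.families.loc[chosen].value_counts()
            for f, n_f in fam_sizes.items():
                assert counts[f] == math.ceil(0.70 * n_f)

    def test_invalid_fraction_rejected(self, nam_pop, qxe_world):
        with pytest.raises(ValueError, match="fraction"):
            crossval(nam_pop, qxe_world["means"], "GN", fraction=1.5)

    def test_null_marker_rarely_accepted(self, small_map):
        """Detection rate of an unlinked null marker concentrates near
        alpha, far below the 30% acceptance threshold."""
        pop = nq.simulate_population(small_map, n_families=5, n_per_family=50,
                                     missing_rate=0.0, seed=64)
        K = nq.compute_kinship(pop)
        null_marker = pop.markers[-1]
        arch = nq.ArchitectureSpec(
            trait="T", mean=50.0, heritability=0.2, residual_sd={"WW": 2.0, "WL": 2.0},
        )
        means = nq.line_means(nq.simulate_phenotypes(pop, arch, kinship=K, seed=65))
        prof = crossval(pop, means, "T", model="qxe", replicates=30, seed=66,
                        markers=[null_marker], kinship=K)
        assert not bool(prof["accepted"].iloc[0])


class TestWindowPeaks:
    def scan_frame(self, rows):
        return pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm", "pvalue"])

    def test_single_marker_is_peak(self):
        peaks = window_peaks(self.scan_frame([("A", 1, 2.0, 0.5)]))
        assert peaks["marker"].tolist() == ["A"]

    def test_min_p_wins(self):
        peaks = window_peaks(
            self.scan_frame([("A", 1, 1.0, 1e-8), ("B", 1, 2.0, 1e-3)])
        )
        assert peaks["marker"].tolist() == ["A"]

    def test_half_open_window_edges(self):
        """Markers at 54.2 and 59.9 cM straddle the [50,55)/[55,60) edge
        and land in different windows."""
        peaks = window_peaks(
            self.scan_frame([("A", 2, 54.2, 1e-4), ("B", 2, 59.9, 1e-6)])
        )
        assert peaks["window_start_cm"].tolist() == [50.0, 55.0]
        assert peaks["marker"].tolist() == ["A", "B"]

    def test_tie_breaking_by_position_then_name(self):
        peaks = window_peaks(
            self.scan_frame([("Z", 1, 1.0, 0.5), ("A", 1, 1.0, 0.5), ("B", 1, 0.5, 0.5)])
        )
        assert peaks["marker"].tolist() == ["B"]


class TestReactionNorms:
    def test_balanced_no_family_effects_equal_raw_means(self, small_map):
        pop = nq.simulate_population(small_map, n_families=4, n_per_family=50,
                                     missing_rate=0.0, seed=70)
        marker = pop.markers[3]
        arch = nq.ArchitectureSpec(
            trait="T", mean=10.0, loci=[nq.QtlEffect(marker, effect=4.0, qxe_wl=3.0)],
            residual_sd={"WW": 1.0, "WL": 1.0},
        )
        means = nq.line_means(nq.simulate_phenotypes(pop, arch, seed=71))
        norms = reaction_norms(pop, means, marker, "T").set_index(["genotype", "environment"])
        merged = means.copy()
        merged["genotype"] = pop.genotypes.loc[merged["line"], marker].to_numpy().astype(int)
        raw = merged.groupby(["genotype", "environment"])["value"].mean()
        for key, value in raw.items():
            assert norms.loc[key, "lsmean"] == pytest.approx(value, abs=0.15)

    def test_wl_protective_allele_reduces_drop(self, nam_pop, nam_kinship):
        """With a wild allele that cushions the WL penalty, the WW->WL drop
        of Hs/Hs carriers is smaller than that of Hv/Hv carriers."""
        marker = nam_pop.markers[12]
        arch = nq.ArchitectureSpec(
            trait="T", mean=100.0, env_effect_wl=-30.0,
            loci=[nq.QtlEffect(marker, effect=0.0, qxe_wl=+12.0)],
            residual_sd={"WW": 2.0, "WL": 2.0},
        )
        means = nq.line_means(nq.simulate_phenotypes(nam_pop, arch, seed=72))
        norms = reaction_norms(nam_pop, means, marker, "T").set_index(["genotype", "environment"])
        drop0 = norms.loc[(0, "WW"), "lsmean"] - norms.loc[(0, "WL"), "lsmean"]
        drop2 = norms.loc[(2, "WW"), "lsmean"] - norms.loc[(2, "WL"), "lsmean"]
        assert drop2 < drop0

    def test_no_effect_classes_equal(self, nam_pop, qxe_world):
        arch = nq.ArchitectureSpec(trait="FLAT", mean=5.0, residual_sd={"WW": 0.5, "WL": 0.5})
        means = nq.line_means(nq.simulate_phenotypes(nam_pop, arch, seed=73))
        marker = nam_pop.markers[6]
        norms = reaction_norms(nam_pop, means, marker, "FLAT")
        ww = norms[norms["environment"] == "WW"].dropna(subset=["lsmean"])
        assert ww["lsmean"].max() - ww["lsmean"].min() < 0.5
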