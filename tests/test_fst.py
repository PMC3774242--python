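"""FST estimators, thinning, and resampling nulls."""

import numpy as np
import pytest

from pleiomap.datatypes import PleiomapError, SNPPanel
from pleiomap.fst import (
    frequency_matched_bootstrap,
    genomewide_fst,
    per_snp_fst,
    permutation_null,
    regional_fst,
    thin_indices,
    thin_snps,
)
from pleiomap.simulate import PanelSimConfig, simulate_accession_panel


def _two_class_matrix(p1, p2, n_per_class=10):
    """Genotypes with exact class frequencies (counts, not draws)."""
    def col(p, n):
        k = int(round(p * n))
        return np.concatenate([np.ones(k), np.zeros(n - k)])
    g = np.concatenate([col(p1, n_per_class), col(p2, n_per_class)])
    labels = np.concatenate([np.ones(n_per_class, dtype=int),
                             np.zeros(n_per_class, dtype=int)])
    return g[:, None], labels


class TestPerSnpFst:
    def test_hand_computed_example(self):
        g, labels = _two_class_matrix(0.2, 0.8)
        res = per_snp_fst(g, labels)
        assert res.per_snp[0] == pytest.approx(0.36, abs=1e-12)

    def test_equal_frequencies_give_zero(self):
        g, labels = _two_class_matrix(0.4, 0.4)
        assert per_snp_fst(g, labels).per_snp[0] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        g, labels = _two_class_matrix(1.0, 0.0)
        assert per_snp_fst(g, labels).per_snp[0] == pytest.approx(1.0)

    def test_closed_form_over_frequency_grid(self):
        """Nei (Ht-Hs)/Ht matches the hand formula on the full grid."""
        n = 10
        for p1 in np.arange(0.0, 1.01, 0.1):
            for p2 in np.arange(0.0, 1.01, 0.1):
                g, labels = _two_class_matrix(p1, p2, n)
                res = per_snp_fst(g, labels)
                pbar = (p1 + p2) / 2
                ht = 2 * pbar * (1 - pbar)
                hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
                if ht == 0:         # monomorphic: skipped
                    assert res.n_snps_skipped == 1
                else:
                    assert res.per_snp[0] == pytest.approx((ht - hs) / ht,
                                                           abs=1e-12)

    def test_monomorphic_and_missing_snps_skipped(self):
        g = np.array([[1, np.nan], [1, np.nan], [1, 0], [1, 1]], dtype=float)
        labels = np.array([1, 1, 0, 0])
        res = per_snp_fst(g, labels)
        assert res.n_snps_skipped == 2          # monomorphic + class empty
        assert res.n_snps_used == 0

    def test_wc_agrees_in_sign_and_converges_for_large_panels(self):
        cfg = PanelSimConfig(n_accessions=800, n_genome_snps=20_000,
                             n_window_snps=0, fst_between_classes=0.1,
                             seed=41)
        panel, _, _ = simulate_accession_panel(cfg)
        nei = genomewide_fst(panel, panel.labels, "nei")
        wc = genomewide_fst(panel, panel.labels, "wc")
        assert nei > 0 and wc > 0
        # two-deme relation: theta ~= 2 G / (1 + G)
        assert wc == pytest.approx(2 * nei / (1 + nei), rel=0.1)

    def test_too_few_accessions_per_class_rejected(self):
        g = np.array([[1.0], [0.0], [1.0]])
        with pytest.raises(PleiomapError):
            per_snp_fst(g, np.array([1, 0, 0]))


class TestGenomewide:
    def test_subset_consistency(self, small_panel):
        _, panel, _, _ = small_panel
        res = per_snp_fst(panel, panel.labels)
        sub = panel.subset_snps(np.arange(0, panel.n_snps, 3))
        res_sub = per_snp_fst(sub, panel.labels)
        expected = np.nanmean(res.per_snp[::3])
        assert res_sub.mean_fst == pytest.approx(expected, abs=1e-12)

    def test_target_fst_recovered(self):
        cfg = PanelSimConfig(n_accessions=400, n_genome_snps=20_000,
                             n_window_snps=0, fst_between_classes=0.2,
                             seed=43)
        panel, _, _ = simulate_accession_panel(cfg)
        assert genomewide_fst(panel, panel.labels) == pytest.approx(0.2,
                                                                    abs=0.01)


class TestPermutationNull:
    def test_differentiated_panel_hits_p_floor(self):
        cfg = PanelSimConfig(n_accessions=200, n_genome_snps=2_000,
                             n_window_snps=0, fst_between_classes=0.1,
                             seed=47)
        panel, _, _ = simulate_accession_panel(cfg)
        null = permutation_null(panel, panel.labels, K=199, seed=3)
        assert null.p_value == pytest.approx(1 / 200)

    def test_p_never_zero_and_seed_reproducible(self, small_panel):
        _, panel, _, _ = small_panel
        a = permutation_null(panel, panel.labels, K=100, seed=5)
        b = permutation_null(panel, panel.labels, K=100, seed=5)
        assert a.p_value > 0
        assert np.array_equal(a.resamples, b.resamples)
        c = permutation_null(panel, panel.labels, K=100, seed=6)
        assert not np.array_equal(a.resamples, c.resamples)

    def test_small_K_rejected(self, small_panel):
        _, panel, _, _ = small_panel
        with pytest.raises(PleiomapError):
            permutation_null(panel, panel.labels, K=50)


class TestThinning:
    def test_hand_example(self):
        chrom = np.array(["1"] * 5, dtype=object)
        pos = np.array([0, 10_000, 49_000, 50_000, 120_000])
        keep = thin_indices(chrom, pos, 50_000)
        assert pos[keep].tolist() == [0, 50_000, 120_000]

    def test_already_sparse_panel_unchanged(self, small_panel):
        _, panel, _, _ = small_panel
        idx = thin_indices(panel.chrom, panel.pos, 1)
        assert idx.size == panel.n_snps

    def test_duplicate_positions_keep_first(self):
        chrom = np.array(["1"] * 3, dtype=object)
        pos = np.array([100, 100, 60_000])
        keep = thin_indices(chrom, pos, 50_000)
        assert keep.tolist() == [0, 2]

    def test_empty_selection_for_empty_chromosome(self):
        keep = thin_indices(np.array([], dtype=object), np.array([]), 50_000)
        assert keep.size == 0

    def test_thin_snps_respects_interval(self, small_panel):
        _, panel, _, _ = small_panel
        thinned = thin_snps(panel, 50_000)
        for c in np.unique(thinned.chrom):
            p = thinned.pos[thinned.chrom == c]
            assert np.all(np.diff(p) >= 50_000)


class TestRegionalFst:
    def test_uniform_frequencies_reproduce_closed_form(self):
        # one cluster, every SNP at the 0.2 / 0.8 frequencies -> FST 0.36
        n = 20
        cols = []
        for _ in range(5):
            g, labels = _two_class_matrix(0.2, 0.8, n // 2)
            cols.append(g[:, 0])
        G = np.column_stack(cols)
        panel = SNPPanel(
            accession_ids=[f"a{i}" for i in range(n)],
            chrom=np.array(["1"] * 5, dtype=object),
            pos=np.arange(5) * 100_000 + 1,
            genotypes=G, labels=labels,
            clusters=np.zeros(n, dtype=int))
        res = regional_fst(panel, labels, interval_bp=50_000)
        assert res["clusters"][0].mean_fst == pytest.approx(0.36, abs=1e-12)

    def test_identical_class_frequencies_give_zero(self):
        n = 20
        g, labels = _two_class_matrix(0.5, 0.5, n // 2)
        panel = SNPPanel(
            accession_ids=[f"a{i}" for i in range(n)],
            chrom=np.array(["1"], dtype=object), pos=np.array([1]),
            genotypes=g, labels=labels, clusters=np.zeros(n, dtype=int))
        res = regional_fst(panel, labels)
        assert res["clusters"][0].mean_fst == pytest.approx(0.0, abs=1e-12)

    def test_single_class_cluster_skipped(self):
        n = 20
        g, labels = _two_class_matrix(0.2, 0.8, n // 2)
        clusters = np.where(labels == 1, 0, 1)       # each cluster one class
        panel = SNPPanel(
            accession_ids=[f"a{i}" for i in range(n)],
            chrom=np.array(["1"], dtype=object), pos=np.array([1]),
            genotypes=g, labels=labels, clusters=clusters)
        res = regional_fst(panel, labels)
        assert not res["clusters"]
        assert sorted(res["skipped"]) == [0, 1]

    def test_differentiated_clusters_detected(self):
        """Clusters with true differentiation show elevated FST."""
        rng = np.random.default_rng(8)
        n_per, n_clusters, m = 40, 6, 400
        rows, labels, clusters = [], [], []
        for c in range(n_clusters):
            y = (rng.random(n_per) < 0.5).astype(int)
            # differentiation in all clusters except the last
            delta = 0.3 if c < n_clusters - 1 else 0.0
            p = np.where(y[:, None] == 1, 0.5 + delta, 0.5 - delta)
            rows.append((rng.random((n_per, m)) < p).astype(float))
            labels.append(y)
            clusters.append(np.full(n_per, c))
        panel = SNPPanel(
            accession_ids=[f"a{i}" for i in range(n_per * n_clusters)],
            chrom=np.array(["1"] * m, dtype=object),
            pos=(np.arange(m) * 60_000 + 1),
            genotypes=np.concatenate(rows),
            labels=np.concatenate(labels),
            clusters=np.concatenate(clusters))
        res = regional_fst(panel, panel.labels, interval_bp=50_000)
        fsts = {c: r.mean_fst for c, r in res["clusters"].items()}
        hot = [c for c, v in fsts.items() if v > 0.05]
        assert sorted(hot) == list(range(n_clusters - 1))


class TestFrequencyMatchedBootstrap:
    def test_filter_postcondition(self, small_panel):
        _, panel, _, _ = small_panel
        null = frequency_matched_bootstrap(panel, panel.labels, n_snps=100,
                                           tolerance=0.05, seed=1)
        assert null.K == 100
        assert null.p_value > 0

    def test_vacuous_tolerance_accepts_all_polymorphic(self, small_panel):
        _, panel, _, _ = small_panel
        with np.errstate(invalid="ignore"):
            p = np.nanmean(panel.genotypes, axis=0)
        n_poly = int(np.sum((p > 0) & (p < 1)))
        null = frequency_matched_bootstrap(panel, panel.labels,
                                           n_snps=n_poly, tolerance=0.5,
                                           seed=2)
        assert null.K == n_poly

    def test_shortfall_reported(self, small_panel):
        _, panel, _, _ = small_panel
        with pytest.raises(PleiomapError, match="required"):
            frequency_matched_bootstrap(panel, panel.labels,
                                        n_snps=10 ** 6, tolerance=0.001)

    def test_differentiated_panel_beats_null(self):
        cfg = PanelSimConfig(n_accessions=200, n_genome_snps=3_000,
                             n_window_snps=0, fst_between_classes=0.15,
                             seed=53)
        panel, _, _ = simulate_accession_panel(cfg)
        null = frequency_matched_bootstrap(panel, panel.labels, n_snps=200,
                                           tolerance=0.1, seed=3)
        assert null.p_value == pytest.approx(1 / 201)
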