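"""Grid construction, genotype probabilities, scans and model selection."""

import numpy as np
import pytest

from pleiomap.datatypes import GeneticMap, PleiomapError, RILPanel
from pleiomap.qtl import (
    build_grid,
    fit_model,
    genotype_probabilities,
    permutation_threshold,
    refine_positions,
    scan_trait,
    scan_trait_imputed,
    stepwise_additive,
)
from pleiomap.simulate import (
    RILSimConfig,
    additive_effect_for_pve,
    ril_recombination_fraction,
    simulate_ril_panel,
)

import pandas as pd


def _panel(gmap, G, phen=None):
    ids = [f"L{i}" for i in range(G.shape[0])]
    phen = phen if phen is not None else pd.DataFrame(index=ids)
    return RILPanel(ids, G, gmap, phen)


class TestBuildGrid:
    def test_even_division(self):
        gmap = GeneticMap(("1",), (("a", "b"),), ((0.0, 10.0),))
        grid = build_grid(gmap, 2.0)
        assert np.allclose(grid.pos, [0, 2, 4, 6, 8, 10])
        assert grid.is_marker.tolist() == [True] + [False] * 4 + [True]

    def test_gap_subdivided_evenly_never_exceeding_step(self):
        gmap = GeneticMap(("1",), (("a", "b"),), ((0.0, 3.0),))
        grid = build_grid(gmap, 2.0)
        assert np.allclose(grid.pos, [0.0, 1.5, 3.0])

    def test_single_marker_chromosome(self):
        gmap = GeneticMap(("1",), (("a",),), ((5.0,),))
        grid = build_grid(gmap, 2.0)
        assert grid.pos.tolist() == [5.0]
        assert grid.is_marker.all()

    def test_all_markers_retained_and_gaps_bounded(self, small_cross):
        _, gmap, _, _ = small_cross
        grid = build_grid(gmap, 2.0)
        assert int(grid.is_marker.sum()) == gmap.n_markers
        for c in gmap.chrom_names:
            p = grid.pos[grid.chrom == c]
            assert np.all(np.diff(p) <= 2.0 + 1e-9)

    def test_nonpositive_step_rejected(self, small_cross):
        _, gmap, _, _ = small_cross
        with pytest.raises(PleiomapError):
            build_grid(gmap, 0.0)


class TestGenotypeProbabilities:
    gmap = GeneticMap(("1",), (("a", "b"),), ((0.0, 20.0),))

    def test_observed_markers_give_zero_or_one(self):
        G = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        grid = build_grid(self.gmap, 2.0)
        pr = genotype_probabilities(_panel(self.gmap, G), grid).probs
        mk = grid.is_marker
        assert np.array_equal(pr[:, mk], G)

    def test_discordant_flanks_midpoint_is_half(self):
        G = np.array([[1.0, 0.0]])
        grid = build_grid(self.gmap, 10.0)          # 0, 10, 20
        pr = genotype_probabilities(_panel(self.gmap, G), grid).probs
        assert pr[0, 1] == pytest.approx(0.5)

    def test_concordant_flanks_symmetric_and_above_half(self):
        G = np.array([[1.0, 1.0]])
        grid = build_grid(self.gmap, 5.0)           # 0, 5, 10, 15, 20
        pr = genotype_probabilities(_panel(self.gmap, G), grid).probs[0]
        assert pr[2] > 0.5
        assert pr[1] == pytest.approx(pr[3], abs=1e-12)

    def test_matches_exhaustive_hidden_state_enumeration(self):
        """Forward-backward on the 2-state chain vs brute-force joint."""
        d = 20.0
        G = np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        grid = build_grid(self.gmap, 10.0)          # midpoint at 10
        pr = genotype_probabilities(_panel(self.gmap, G), grid,
                                    map_scale="ril").probs[:, 1]
        # brute force: enumerate hidden state h at the midpoint
        from pleiomap.qtl import _recomb_fraction
        R = float(_recomb_fraction(np.asarray(10.0), "ril"))
        for row, p_impl in zip(G, pr):
            gl, gr = row
            joint = {}
            for h in (0.0, 1.0):
                t1 = 1 - R if h == gl else R
                t2 = 1 - R if h == gr else R
                joint[h] = 0.5 * t1 * t2
            expected = joint[1.0] / (joint[0.0] + joint[1.0])
            assert p_impl == pytest.approx(expected, abs=1e-12)

    def test_fully_missing_line_falls_back_to_half(self):
        G = np.array([[np.nan, np.nan], [1.0, 1.0]])
        grid = build_grid(self.gmap, 2.0)
        res = genotype_probabilities(_panel(self.gmap, G), grid)
        assert np.allclose(res.probs[0], 0.5)
        assert res.n_uninformative == 1

    def test_partial_missing_conditions_on_nearest_informative(self):
        gmap = GeneticMap(("1",), (("a", "b", "c"),), ((0.0, 10.0, 20.0),))
        G = np.array([[1.0, np.nan, 1.0]])
        grid = build_grid(gmap, 10.0)
        pr = genotype_probabilities(_panel(gmap, G), grid).probs[0]
        # at the masked middle marker the flanks (both A, 10 cM away) agree
        assert pr[1] > 0.5


class TestScan:
    def test_constant_phenotype_gives_zero_profile(self, small_cross):
        _, gmap, panel, _ = small_cross
        grid = build_grid(gmap)
        probs = genotype_probabilities(panel, grid)
        with pytest.warns(UserWarning):
            prof = scan_trait(probs, np.ones(panel.n_lines))
        assert np.all(prof.lod == 0)

    def test_perfect_determination_caps_at_marker(self, small_cross):
        _, gmap, panel, _ = small_cross
        grid = build_grid(gmap)
        probs = genotype_probabilities(panel, grid)
        j = np.flatnonzero(grid.is_marker)[10]
        y = probs.probs[:, j].copy()
        prof = scan_trait(probs, y)
        assert int(np.argmax(prof.lod)) == j
        assert prof.max_lod > 100          # RSS floored, LOD finite but large

    def test_lod_matches_least_squares_oracle_at_markers(self, small_cross):
        """Scan LOD at observed markers == closed-form regression LOD."""
        _, gmap, panel, _ = small_cross
        grid = build_grid(gmap)
        probs = genotype_probabilities(panel, grid)
        y = panel.phenotypes["WUE"].to_numpy()
        prof = scan_trait(probs, y)
        n = y.size
        rss0 = np.sum((y - y.mean()) ** 2)
        for j in np.flatnonzero(grid.is_marker)[::7]:
            X = np.column_stack([np.ones(n), probs.probs[:, j]])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = np.sum((y - X @ beta) ** 2)
            lod = (n / 2) * np.log10(rss0 / rss1)
            assert prof.lod[j] == pytest.approx(lod, abs=1e-8)

    def test_imputation_engine_agrees_roughly_with_hk(self, small_cross):
        _, gmap, panel, _ = small_cross
        grid = build_grid(gmap)
        probs = genotype_probabilities(panel, grid)
        y = panel.phenotypes["WUE"].to_numpy()
        hk = scan_trait(probs, y)
        mi = scan_trait_imputed(probs, y, n_draws=64, seed=1)
        assert mi.argmax[0] == hk.argmax[0]
        assert abs(mi.max_lod - hk.max_lod) / hk.max_lod < 0.2


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum_of_maxima(self, small_cross):
        _, gmap, panel, _ = small_cross
        grid = build_grid(gmap)
        probs = genotype_probabilities(panel, grid)
        y = panel.phenotypes["WUE"].to_numpy()
        thr = permutation_threshold(probs, y, n_perm=100, alpha=1.0, seed=0)
        thr05 = permutation_threshold(probs, y, n_perm=100, alpha=0.05, seed=0)
        assert thr < thr05

    def test_same_seed_identical_thresholds(self, small_cross):
        _, gmap, panel, _ = small_cross
        grid = build_grid(gmap)
        probs = genotype_probabilities(panel, grid)
        y = panel.phenotypes["FT"].to_numpy()
        a = permutation_threshold(probs, y, n_perm=200, seed=42)
        b = permutation_threshold(probs, y, n_perm=200, seed=42)
        assert a == b
        c = permutation_threshold(probs, y, n_perm=200, seed=43)
        assert a != c

    def test_invalid_inputs_rejected(self, small_cross):
        _, gmap, panel, _ = small_cross
        grid = build_grid(gmap)
        probs = genotype_probabilities(panel, grid)
        y = panel.phenotypes["WUE"].to_numpy()
        with pytest.raises(PleiomapError):
            permutation_threshold(probs, y, n_perm=50)
        with pytest.raises(PleiomapError):
            permutation_threshold(probs, y, n_perm=100, alpha=1.5)


@pytest.fixture(scope="module")
def scanned():
    a = additive_effect_for_pve(0.20)
    cfg = RILSimConfig(
        qtl_specs=(("1", 30.0, a, 0.0), ("3", 50.0, a, 0.0)), seed=99)
    gmap, panel, truth = simulate_ril_panel(cfg)
    grid = build_grid(gmap)
    probs = genotype_probabilities(panel, grid)
    y = panel.phenotypes["WUE"].to_numpy()
    return probs, y


def _nearest_grid(grid, chrom, pos):
    idx = grid.chrom_index(chrom)
    j = idx[np.argmin(np.abs(grid.pos[idx] - pos))]
    return str(grid.chrom[j]), float(grid.pos[j])


class TestStepwiseAndFit:

    def test_two_unlinked_qtls_recovered(self, scanned):
        probs, y = scanned
        model = stepwise_additive(probs, y, penalty=2.6)
        found = {(q.chrom, q.pos_cM) for q in model.qtls}
        for true_c, true_p in (("1", 30.0), ("3", 50.0)):
            assert any(c == true_c and abs(p - true_p) <= 10
                       for c, p in found)

    def test_infinite_penalty_gives_empty_model(self, scanned):
        probs, y = scanned
        model = stepwise_additive(probs, y, penalty=np.inf)
        assert model.size == 0
        assert model.model_lod == 0.0

    def test_effect_and_pve_recovery(self):
        a = additive_effect_for_pve(0.25)
        cfg = RILSimConfig(n_lines=2000, qtl_specs=(("4", 4.0, a, 0.0),),
                           seed=17)
        gmap, panel, _ = simulate_ril_panel(cfg)
        grid = build_grid(gmap)
        probs = genotype_probabilities(panel, grid)
        y = panel.phenotypes["WUE"].to_numpy()
        model = stepwise_additive(probs, y, penalty=2.6)
        q = max(model.qtls, key=lambda q: q.pve)
        assert q.effect == pytest.approx(a, rel=0.15)
        assert q.pve == pytest.approx(25.0, abs=4.0)

    def test_refinement_never_decreases_model_lod(self, scanned):
        probs, y = scanned
        from pleiomap.datatypes import QTL, QTLModel
        # deliberately mis-initialized positions near the true QTLs
        init = QTLModel([QTL(*_nearest_grid(probs.grid, "1", 38.0)),
                         QTL(*_nearest_grid(probs.grid, "3", 42.0))])
        fitted0 = fit_model(init, probs, y)
        refined = refine_positions(init, probs, y)
        fitted1 = fit_model(refined, probs, y)
        assert fitted1.model_lod >= fitted0.model_lod - 1e-9

    def test_refined_single_qtl_matches_scan_argmax(self, scanned):
        probs, y = scanned
        from pleiomap.datatypes import QTL, QTLModel
        prof = scan_trait(probs, y)
        init = QTLModel([QTL(*_nearest_grid(probs.grid, "1", 0.0))])
        refined = refine_positions(init, probs, y)
        c, p = prof.argmax
        assert (refined.qtls[0].chrom, refined.qtls[0].pos_cM) == (c, p)

    def test_empty_model_fit(self, scanned):
        probs, y = scanned
        from pleiomap.datatypes import QTLModel
        fitted = fit_model(QTLModel([]), probs, y)
        assert fitted.size == 0 and fitted.model_pve == 0.0

    def test_null_data_rarely_yields_qtls(self):
        """Stepwise under pure noise stays empty in most replicates."""
        hits = 0
        reps = 25
        for rep in range(reps):
            cfg = RILSimConfig(qtl_specs=(), seed=3000 + rep)
            gmap, panel, _ = simulate_ril_panel(cfg)
            grid = build_grid(gmap)
            probs = genotype_probabilities(panel, grid)
            y = panel.phenotypes["WUE"].to_numpy()
            thr = permutation_threshold(probs, y, n_perm=200, seed=rep)
            model = stepwise_additive(probs, y, penalty=thr)
            hits += model.size == 0
        assert hits >= int(0.9 * reps) - 2
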