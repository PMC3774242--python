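"""Window extraction, classifier protocols and label imputation."""

import numpy as np
import pytest

from pleiomap.datatypes import LABEL_UNKNOWN, PleiomapError, SNPPanel
from pleiomap.impute import (
    ClassifierSpec,
    extract_window,
    impute_labels,
    kfold_cv,
    subset_loocv,
    train_classifier,
)

SMALL_SPEC = ClassifierSpec(widths=(2.0 ** -4, 1.0),
                            regularizations=(1.0, 2.0 ** 4),
                            inner_folds=2, seed=0)


def _panel_at_offsets(offsets, n=8, focal=500_000):
    pos = np.array(sorted(focal + o for o in offsets))
    G = np.tile(np.arange(n) % 2, (pos.size, 1)).T.astype(float)
    return SNPPanel(
        accession_ids=[f"a{i}" for i in range(n)],
        chrom=np.array(["4"] * pos.size, dtype=object),
        pos=pos, genotypes=G,
        labels=np.arange(n) % 2)


class TestExtractWindow:
    def test_closed_interval_boundaries(self):
        panel = _panel_at_offsets([-120_000, -100_000, 0, 99_000, 101_000])
        w = extract_window(panel, "4", 500_000, 100_000)
        assert sorted(w.snp_pos - 500_000) == [-100_000, 0, 99_000]

    def test_zero_half_span_keeps_exact_matches_only(self):
        panel = _panel_at_offsets([-1, 0, 1])
        w = extract_window(panel, "4", 500_000, 0)
        assert w.snp_pos.tolist() == [500_000]

    def test_no_missing_features_equal_genotypes(self, small_panel):
        cfg, panel, _, truth = small_panel
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        win = np.asarray(truth.extra["window_snps"])
        assert np.array_equal(w.X, panel.genotypes[:, win])
        assert w.n_missing_filled == 0

    def test_missing_filled_with_major_allele(self):
        panel = _panel_at_offsets([0, 10])
        panel.genotypes[0, 0] = np.nan
        w = extract_window(panel, "4", 500_000, 100_000)
        assert w.n_missing_filled == 1
        assert not np.isnan(w.X).any()

    def test_empty_window_rejected(self):
        panel = _panel_at_offsets([200_000])
        with pytest.raises(PleiomapError):
            extract_window(panel, "4", 500_000, 100_000)


class TestClassifier:
    def test_perfect_tag_reaches_full_accuracy(self, perfect_tag_panel):
        cfg, panel, _, _ = perfect_tag_panel
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        rep = kfold_cv(w, panel.labels, k=4, spec=SMALL_SPEC, seed=1)
        assert rep.mean_accuracy == 1.0
        rep2 = subset_loocv(w, panel.labels, n=12, repeats=3,
                            spec=SMALL_SPEC, seed=1)
        assert rep2.mean_accuracy == 1.0

    def test_label_permutation_recovers_majority_baseline(self, small_panel):
        """No leakage: CV accuracy on permuted labels ~ majority class."""
        cfg, panel, _, _ = small_panel
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        rng = np.random.default_rng(2)
        perm = rng.permutation(panel.labels)
        rep = kfold_cv(w, perm, k=4, spec=SMALL_SPEC, seed=2)
        base = max(np.mean(perm == 1), np.mean(perm == 0))
        se = np.sqrt(base * (1 - base) / perm.size)
        assert rep.mean_accuracy <= base + 4 * se

    def test_fixed_seed_reports_identical(self, small_panel):
        cfg, panel, _, _ = small_panel
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        a = subset_loocv(w, panel.labels, n=10, repeats=3,
                         spec=SMALL_SPEC, seed=7)
        b = subset_loocv(w, panel.labels, n=10, repeats=3,
                         spec=SMALL_SPEC, seed=7)
        assert a == b

    def test_grid_search_tie_break_is_deterministic(self, perfect_tag_panel):
        cfg, panel, _, _ = perfect_tag_panel
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        t1 = train_classifier(w, panel.labels, SMALL_SPEC)
        t2 = train_classifier(w, panel.labels, SMALL_SPEC)
        assert (t1.width, t1.regularization) == (t2.width, t2.regularization)
        # perfect tag: every grid point ties at accuracy 1 -> smallest chosen
        assert t1.regularization == min(SMALL_SPEC.regularizations)
        assert t1.width == min(SMALL_SPEC.widths)

    def test_single_class_labels_rejected(self, small_panel):
        cfg, panel, _, _ = small_panel
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        with pytest.raises(PleiomapError):
            train_classifier(w, np.ones_like(panel.labels), SMALL_SPEC)

    def test_full_subset_reduces_to_plain_loocv(self, perfect_tag_panel):
        """n = all labeled accessions, repeats = 1: the subset draw is a
        permutation, so the fold set — and hence the accuracy — is plain
        leave-one-out regardless of the seed."""
        cfg, panel, _, _ = perfect_tag_panel
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        n_labeled = int(np.sum(panel.labels >= 0))
        a = subset_loocv(w, panel.labels, n=n_labeled, repeats=1,
                         spec=SMALL_SPEC, seed=1)
        b = subset_loocv(w, panel.labels, n=n_labeled, repeats=1,
                         spec=SMALL_SPEC, seed=2)
        assert a.mean_accuracy == b.mean_accuracy

    def test_subset_larger_than_labeled_rejected(self, small_panel):
        cfg, panel, _, _ = small_panel
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        with pytest.raises(PleiomapError):
            subset_loocv(w, panel.labels, n=10_000, spec=SMALL_SPEC)


class TestImputeLabels:
    def test_unlabeled_get_predictions_with_consistent_margins(
            self, perfect_tag_panel):
        cfg, panel, _, truth = perfect_tag_panel
        labels = panel.labels.copy()
        hidden = np.arange(0, labels.size, 3)
        true_hidden = labels[hidden].copy()
        labels[hidden] = LABEL_UNKNOWN
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        trained = train_classifier(w, labels, SMALL_SPEC)
        out, margins = impute_labels(trained, w, labels)
        # perfect tag: hidden labels recovered exactly
        assert np.array_equal(out[hidden], true_hidden)
        # margin sign agrees with the predicted class
        m = margins[hidden]
        assert np.all((m > 0) == (out[hidden] == 1))
        # observed labels untouched, margins undefined there
        keep = np.setdiff1d(np.arange(labels.size), hidden)
        assert np.array_equal(out[keep], labels[keep])
        assert np.all(np.isnan(margins[keep]))

    def test_imputed_classes_reproduce_true_fst(self):
        """End-to-end: FST between imputed classes tracks the truth."""
        from pleiomap.fst import genomewide_fst
        from pleiomap.simulate import PanelSimConfig, simulate_accession_panel
        cfg = PanelSimConfig(n_accessions=300, n_genome_snps=3000,
                             tag_ld_r2=0.9, fst_between_classes=0.1, seed=71)
        panel, _, truth = simulate_accession_panel(cfg)
        true_fst = genomewide_fst(panel, panel.labels)
        labels = panel.labels.copy()
        rng = np.random.default_rng(5)
        hidden = rng.choice(labels.size, size=150, replace=False)
        labels[hidden] = LABEL_UNKNOWN
        w = extract_window(panel, cfg.focal_chrom, cfg.focal_pos_bp)
        trained = train_classifier(w, labels, SMALL_SPEC)
        out, _ = impute_labels(trained, w, labels)
        imputed_fst = genomewide_fst(panel, out)
        assert imputed_fst == pytest.approx(true_fst, abs=0.02)
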