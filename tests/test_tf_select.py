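"""Stability selection: frequencies, cutoff optimisation, recovery."""

import numpy as np
import pandas as pd
import pytest

from dysreg import (
    SelectionParams,
    SyntheticConfig,
    generate_cohort,
    optimize_frequency_cutoff,
    select_tfs_for_gene,
    selection_frequencies,
)
from dysreg.errors import InputError
from dysreg.lasso import PathParams, RegressionDesign, build_design, lambda_max


def _design(rng, n=120, k=8, beta=None, noise=0.5):
    X = rng.normal(size=(n, k + 2))
    if beta is None:
        beta = np.zeros(k + 2)
    y = X @ beta + rng.normal(0, noise, n)
    return RegressionDesign(
        gene="g", y=y, x_cna=X[:, 0], x_dm=X[:, 1], tf_matrix=X[:, 2:],
        tf_names=[f"T{i}" for i in range(k)],
    )


class TestFrequencies:
    def test_always_active_tf_counts_every_lambda(self, rng):
        beta = np.zeros(10)
        beta[:2] = [0.5, -0.5]
        beta[2] = 2.0  # T0 dominates: active over the whole usable path
        d = _design(rng, beta=beta, noise=0.3)
        lams = np.geomspace(lambda_max(d) * 0.5, lambda_max(d) * 0.05, 7)
        freq = selection_frequencies(d, lams)
        assert freq["T0"] == len(lams)

    def test_never_active_tf_counts_zero(self, rng):
        beta = np.zeros(10)
        beta[2] = 2.0
        d = _design(rng, beta=beta, noise=0.1)
        lams = np.full(5, lambda_max(d) * 0.9)
        freq = selection_frequencies(d, lams)
        assert freq.drop("T0").eq(0).all()

    def test_duplicate_lambdas_count_with_multiplicity(self, rng):
        beta = np.zeros(10)
        beta[2] = 1.0
        d = _design(rng, beta=beta, noise=0.2)
        lam = lambda_max(d) * 0.2
        freq = selection_frequencies(d, np.array([lam, lam, lam]))
        assert freq["T0"] == 3

    def test_empty_lambda_list_rejected(self, rng):
        with pytest.raises(InputError):
            selection_frequencies(_design(rng), np.array([]))


class TestCutoffOptimisation:
    def test_strong_tf_kept_noise_dropped(self, rng):
        beta = np.zeros(10)
        beta[:2] = [0.5, -0.5]
        beta[2] = 1.5
        d = _design(rng, n=200, beta=beta, noise=0.4)
        freq = pd.Series(0, index=d.tf_names)
        freq["T0"] = 10  # stable signal
        freq["T5"] = 1   # churn
        cutoff, mse = optimize_frequency_cutoff(d, freq, splits=30, seed=2)
        selected = {t for t in d.tf_names if freq[t] > cutoff}
        assert selected == {"T0"}
        assert set(mse) == {0, 1, 10}

    def test_single_shared_frequency_keeps_useful_tfs(self, rng):
        """When every ever-selected TF has the same frequency the grid still
        contains cutoff 0, so the model keeping them is evaluated."""
        beta = np.zeros(10)
        beta[2:4] = [1.5, -1.2]
        d = _design(rng, n=200, beta=beta, noise=0.4)
        freq = pd.Series(0, index=d.tf_names)
        freq[["T0", "T1"]] = 10
        cutoff, mse = optimize_frequency_cutoff(d, freq, splits=30, seed=2)
        assert cutoff == 0
        assert set(mse) == {0, 10}

    def test_exact_mse_tie_prefers_larger_cutoff(self, rng):
        """A TF column duplicating the copy-number column changes no OLS
        prediction, so both cutoffs give identical MSE and the parsimonious
        one wins."""
        n, k = 60, 3
        X = rng.normal(size=(n, 2))
        tf = np.column_stack([X[:, 0], rng.normal(size=(n, k - 1))])
        y = X @ np.array([1.0, -0.5]) + rng.normal(0, 0.3, n)
        d = RegressionDesign(gene="g", y=y, x_cna=X[:, 0], x_dm=X[:, 1],
                             tf_matrix=tf, tf_names=["DUP", "N1", "N2"])
        freq = pd.Series({"DUP": 4, "N1": 0, "N2": 0})
        cutoff, mse = optimize_frequency_cutoff(d, freq, splits=10, seed=3)
        assert mse[0] == pytest.approx(mse[4], rel=1e-9)
        assert cutoff == 4

    def test_no_positive_frequency_rejected(self, rng):
        d = _design(rng)
        with pytest.raises(InputError):
            optimize_frequency_cutoff(d, pd.Series(0, index=d.tf_names))


class TestSelectTfsForGene:
    def test_same_seed_same_profile(self, small_cohort, quick_selection_params):
        bundle, _ = small_cohort
        gene = bundle.panel_genes[0]
        p1 = select_tfs_for_gene(bundle, gene, quick_selection_params)
        p2 = select_tfs_for_gene(bundle, gene, quick_selection_params)
        assert p1.selected_tfs == p2.selected_tfs
        assert p1.optimal_cutoff == p2.optimal_cutoff
        pd.testing.assert_series_equal(p1.frequency, p2.frequency)
        np.testing.assert_array_equal(p1.lambdas, p2.lambdas)

    def test_selected_set_matches_cutoff_rule(self, small_cohort,
                                              quick_selection_params):
        bundle, _ = small_cohort
        prof = select_tfs_for_gene(bundle, bundle.panel_genes[1],
                                   quick_selection_params)
        rule = {t for t, f in prof.frequency.items() if f > prof.optimal_cutoff}
        assert prof.selected_tfs == rule
        assert prof.frequency.between(0, prof.runs).all()

    def test_planted_tfs_recovered(self, small_cohort, quick_selection_params):
        bundle, truth = small_cohort
        hits = total = 0
        for gene in bundle.panel_genes[:4]:
            prof = select_tfs_for_gene(bundle, gene, quick_selection_params)
            hits += len(prof.selected_tfs & truth.true_tf_sets[gene])
            total += len(truth.true_tf_sets[gene])
        assert hits / total >= 0.9

    def test_recall_does_not_degrade_with_more_samples(self):
        recalls = []
        for n in (100, 400):
            recall = []
            for seed in (1, 2, 3):
                cfg = SyntheticConfig(
                    n_tumour=n, n_normal=20, n_panel_genes=3, n_tfs=30,
                    true_tfs_per_gene=3, seed=seed,
                )
                bundle, truth = generate_cohort(cfg)
                params = SelectionParams(runs=8, splits=8, seed=seed,
                                         path=PathParams(n_points=50, folds=5))
                for gene in bundle.panel_genes:
                    prof = select_tfs_for_gene(bundle, gene, params)
                    tset = truth.true_tf_sets[gene]
                    recall.append(len(prof.selected_tfs & tset) / len(tset))
            recalls.append(np.mean(recall))
        assert recalls[1] >= recalls[0] - 0.05

    def test_pure_noise_gene_selects_almost_nothing(self):
        cfg = SyntheticConfig(
            n_tumour=150, n_normal=20, n_panel_genes=6, n_tfs=40,
            true_tfs_per_gene=2, tf_effect_range=(0.0, 0.0),
            tf_shift_fraction=0.0, seed=29,
        )
        bundle, _ = generate_cohort(cfg)
        params = SelectionParams(runs=10, splits=10, seed=3,
                                 path=PathParams(n_points=60, folds=5))
        sizes = [
            len(select_tfs_for_gene(bundle, g, params).selected_tfs)
            for g in bundle.panel_genes
        ]
        assert np.median(sizes) <= 2
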