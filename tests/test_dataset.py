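"""Decoy matching, stratified folds, and synthetic fixture generators."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from fpgan.dataset import (
    ACTIVE,
    INACTIVE,
    PropertyTable,
    make_synthetic_fpset,
    make_synthetic_library,
    make_two_signature_fpset,
    match_decoys,
    read_label_table,
    stratified_kfold,
)
from fpgan.fingerprints import confirm_substructure


def _bimodal_pool(n_per_mode=500, seed=0):
    """Pool with MW modes at 150 and 300; actives sit at the 300 mode.

    logP tracks MW (as it does in real compound collections), so the first
    principal component of the standardized property pair is well defined.
    """
    rng = np.random.default_rng(seed)
    mw = np.concatenate([rng.normal(150, 10, n_per_mode),
                         rng.normal(300, 10, n_per_mode)])
    logp = mw / 100.0 + rng.normal(0, 0.5, 2 * n_per_mode)
    ids = [f"pool_{i}" for i in range(2 * n_per_mode)]
    pool = PropertyTable(ids, mw, logp)
    act_mw = rng.normal(300, 10, 400)
    act = PropertyTable(
        [f"act_{i}" for i in range(400)],
        act_mw,
        act_mw / 100.0 + rng.normal(0, 0.5, 400),
    )
    return act, pool


class TestMatchDecoys:
    def test_prefers_matching_mode(self):
        act, pool = _bimodal_pool()
        chosen = match_decoys(act, pool, n_select=200, seed=1)
        # pool ids >= 500 belong to the MW~300 mode
        frac_300 = np.mean([int(c.split("_")[1]) >= 500 for c in chosen])
        assert frac_300 >= 0.8

    def test_full_pool_returned_when_n_equals_pool(self):
        act, pool = _bimodal_pool(n_per_mode=50)
        chosen = match_decoys(act, pool, n_select=100, seed=0)
        assert sorted(chosen) == sorted(pool.ids)

    def test_oversized_request_rejected(self):
        act, pool = _bimodal_pool(n_per_mode=10)
        with pytest.raises(ValueError):
            match_decoys(act, pool, n_select=50, seed=0)

    def test_degenerate_property_column_rejected(self):
        act = PropertyTable(["a", "b"], [300.0, 300.0], [2.0, 2.0])
        pool = PropertyTable(["p", "q", "r"], [300.0, 300.0, 300.0],
                             [2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            match_decoys(act, pool, n_select=2, seed=0)

    def test_halves_ks_distance_vs_random_subset(self):
        """Density matching at least halves the MW KS distance to actives
        relative to uniformly random subsets (averaged over repeats)."""
        act, pool = _bimodal_pool()
        mw_by_id = dict(zip(pool.ids, pool.mw))
        ks_matched, ks_random = [], []
        for seed in range(30):
            chosen = match_decoys(act, pool, n_select=200, seed=seed)
            ks_matched.append(ks_2samp([mw_by_id[c] for c in chosen], act.mw).statistic)
            rng = np.random.default_rng(seed + 1000)
            rand = rng.choice(pool.ids, size=200, replace=False)
            ks_random.append(ks_2samp([mw_by_id[c] for c in rand], act.mw).statistic)
        assert np.mean(ks_matched) <= 0.5 * np.mean(ks_random)

    def test_uniform_pool_selection_close_to_random(self):
        """When actives and pool share one distribution the weights are
        nearly flat, so the selected subset is statistically plain."""
        rng = np.random.default_rng(3)
        act = PropertyTable([f"a{i}" for i in range(500)],
                            rng.normal(300, 30, 500), rng.normal(2, 1, 500))
        pool = PropertyTable([f"p{i}" for i in range(1000)],
                             rng.normal(300, 30, 1000), rng.normal(2, 1, 1000))
        chosen = match_decoys(act, pool, n_select=400, seed=0)
        mw_by_id = dict(zip(pool.ids, pool.mw))
        ks = ks_2samp([mw_by_id[c] for c in chosen], pool.mw).statistic
        assert ks < 0.1


class TestStratifiedKFold:
    def test_tiny_exact_balance(self):
        labels = np.array([ACTIVE] * 10 + [INACTIVE] * 10)
        fa = stratified_kfold(labels, k=10, seed=0)
        for f in range(10):
            test = fa.test_indices(f)
            assert len(test) == 2
            assert labels[test].sum() == 1

    def test_published_class_sizes_partition(self):
        """7,002 actives + 9,998 decoys split 10-fold: folds of 1,700 with
        700 or 701 actives each."""
        labels = np.array([ACTIVE] * 7002 + [INACTIVE] * 9998)
        fa = stratified_kfold(labels, k=10, seed=0)
        all_test = np.concatenate([fa.test_indices(f) for f in range(10)])
        assert sorted(all_test) == list(range(17000))
        for f in range(10):
            test = fa.test_indices(f)
            assert len(test) == 1700
            assert labels[test].sum() in (700, 701)

    def test_deterministic_under_seed(self):
        labels = np.array([ACTIVE] * 40 + [INACTIVE] * 60)
        a = stratified_kfold(labels, k=5, seed=7)
        b = stratified_kfold(labels, k=5, seed=7)
        assert np.array_equal(a.fold, b.fold)

    def test_small_class_rejected(self):
        labels = np.array([ACTIVE] * 3 + [INACTIVE] * 50)
        with pytest.raises(ValueError):
            stratified_kfold(labels, k=5, seed=0)


class TestSyntheticFpset:
    def test_extreme_probabilities_are_separable(self):
        data = make_synthetic_fpset(n_active=100, n_inactive=100,
                                    p_on_active=1.0, p_on_inactive=0.0,
                                    background_p=0.0, seed=0)
        sig_pop = data.fingerprints[:, :20].sum(axis=1)
        assert (sig_pop[data.labels == ACTIVE] == 20).all()
        assert (sig_pop[data.labels == INACTIVE] == 0).all()

    def test_equal_probabilities_remove_class_signal(self):
        data = make_synthetic_fpset(n_active=3000, n_inactive=3000,
                                    p_on_active=0.5, p_on_inactive=0.5,
                                    seed=0)
        fa = data.fingerprints[data.labels == ACTIVE].mean(axis=0)
        fi = data.fingerprints[data.labels == INACTIVE].mean(axis=0)
        assert np.abs(fa - fi).max() < 0.06

    def test_default_fixture_supports_a_strong_stump(self, default_fpset):
        """A depth-1 stump on one signature bit reaches the closed-form
        Bernoulli accuracy 0.5*(0.9 + 1-0.1) = 0.9, well above 0.85."""
        data = default_fpset
        bit = data.fingerprints[:, 0]
        acc = max(
            ((bit == 1) == (data.labels == ACTIVE)).mean(),
            ((bit == 0) == (data.labels == ACTIVE)).mean(),
        )
        assert acc >= 0.85

    def test_bit_reproducible(self):
        a = make_synthetic_fpset(n_active=50, n_inactive=50, seed=9)
        b = make_synthetic_fpset(n_active=50, n_inactive=50, seed=9)
        assert np.array_equal(a.fingerprints, b.fingerprints)
        assert a.ids == b.ids

    def test_two_signature_blocks_oppose(self):
        data = make_two_signature_fpset(n_per_class=500, seed=0)
        act = data.fingerprints[data.labels == ACTIVE]
        inact = data.fingerprints[data.labels == INACTIVE]
        assert act[:, :20].mean() > 0.8 and act[:, 20:40].mean() < 0.2
        assert inact[:, 20:40].mean() > 0.8 and inact[:, :20].mean() < 0.2


class TestSyntheticLibrary:
    def test_fraction_one_all_contain_core(self):
        records, truth = make_synthetic_library(n=40, fraction_with_core=1.0,
                                                seed=0)
        assert truth.all()

    def test_fraction_zero_none_contain_core(self):
        records, truth = make_synthetic_library(n=40, fraction_with_core=0.0,
                                                seed=0)
        assert not truth.any()

    def test_ground_truth_matches_subgraph_check(self, planted_library):
        from fpgan.dataset import DEFAULT_CORE_SMILES

        records, truth = planted_library
        recomputed = np.array([
            confirm_substructure(DEFAULT_CORE_SMILES, rec)
            for rec in records[:200]
        ])
        assert np.array_equal(recomputed, truth[:200])

    def test_smiles_all_parse(self, planted_library):
        records, _ = planted_library
        for rec in records[:100]:
            rec.to_mol()  # raises on failure

    def test_invalid_core_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_library(n=5, planted_core_smarts="][")


class TestLabelTable:
    def test_roundtrip_with_computed_properties(self, tmp_path):
        path = tmp_path / "labels.csv"
        path.write_text(
            "id,smiles,label\nm1,CCO,active\nm2,c1ccccc1,inactive\n")
        records, labels, props = read_label_table(path)
        assert [r.molecule_id for r in records] == ["m1", "m2"]
        assert labels.tolist() == [ACTIVE, INACTIVE]
        assert props.mw[1] == pytest.approx(78.11, abs=0.01)
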