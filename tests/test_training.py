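"""Balanced sampling, splits, metrics, and the training loop."""

import numpy as np
import pytest

from graphphos.model import ModelConfig, PredictionResult, SiteSet
from graphphos.synthetic import SyntheticSpec, generate_corpus
from graphphos.experiments import corpus_examples
from graphphos.training import (MetricsReport, build_balanced_sites, evaluate,
                                metrics_from_counts, predict,
                                run_ablation_suite, split_by_family,
                                split_by_plddt, split_random, train)


class TestBalancedSampling:
    def test_toy_protein_bookkeeping(self):
        # "SASTSY": S positives at 0 and 2 leave a single S candidate (4),
        # so strict per-type matching takes it with a shortage warning
        with pytest.warns(UserWarning, match="residue type S"):
            sites = build_balanced_sites([("p", "SASTSY", {0, 2})], seed=0)["p"]
        assert (sites.labels == 1).sum() == 2
        assert (sites.labels == 0).sum() == 1
        assert sites.site_indices[sites.labels == 0].tolist() == [4]
        sites.validate_against("SASTSY")

    def test_seeded_sampling_is_reproducible(self):
        proteins = [("p", "ST" * 30, {0, 4, 8})]
        a = build_balanced_sites(proteins, seed=5)["p"]
        b = build_balanced_sites(proteins, seed=5)["p"]
        np.testing.assert_array_equal(a.site_indices, b.site_indices)
        c = build_balanced_sites(proteins, seed=6)["p"]
        assert not np.array_equal(a.site_indices, c.site_indices)

    def test_global_balance_on_synthetic_corpus(self):
        # sequence_only corpora have ~20-30% positive sites, so every
        # residue type has enough negative candidates for exact balance
        corpus = generate_corpus(SyntheticSpec(
            n_proteins=10, signal_mode="sequence_only", seed=1))
        proteins = [(p.protein_id, p.sequence,
                     {int(i) for i, l in zip(p.site_set.site_indices,
                                             p.site_set.labels) if l == 1})
                    for p in corpus]
        n_pos = sum(len(pos) for _, _, pos in proteins)
        balanced = build_balanced_sites(proteins, seed=0)
        n_neg = sum(int((s.labels == 0).sum()) for s in balanced.values())
        n_pos_out = sum(int((s.labels == 1).sum()) for s in balanced.values())
        assert n_pos_out == n_pos
        assert n_neg == n_pos

    def test_stratification_matches_residue_types(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ASTYG"), size=200))
        pos = {i for i, aa in enumerate(seq) if aa == "S" and rng.random() < 0.4}
        balanced = build_balanced_sites([("p", seq, pos)], seed=0)["p"]
        negs = [seq[i] for i, l in zip(balanced.site_indices, balanced.labels)
                if l == 0]
        assert set(negs) == {"S"}  # S positives draw only S negatives

    def test_candidate_shortage_warns_and_takes_all(self):
        with pytest.warns(UserWarning, match="taking all"):
            sites = build_balanced_sites([("p", "SSSY", {0, 1, 2})], seed=0)["p"]
        assert (sites.labels == 0).sum() == 0  # no S negatives exist


class TestSplits:
    def test_random_split_sizes_and_disjointness(self):
        ids = [f"p{i}" for i in range(10)]
        train, test = split_random(ids, 7, seed=0)
        assert len(train) == 7 and len(test) == 3
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(ids)

    def test_random_split_reproducible(self):
        ids = [f"p{i}" for i in range(20)]
        assert split_random(ids, 12, seed=3) == split_random(ids, 12, seed=3)

    def test_random_split_exhaustive_over_many_corpora(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n = int(rng.integers(3, 30))
            ids = [f"p{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            train, test = split_random(ids, k, seed=trial)
            assert sorted(train + test) == sorted(ids)
            assert not set(train) & set(test)

    def test_random_split_range_validation(self):
        with pytest.raises(ValueError):
            split_random(["a", "b"], 2, seed=0)

    def test_family_greedy_fill(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "c1"]
        fams = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "c1": "C"}
        train, test = split_by_family(ids, fams, n_train=5)
        assert sorted(train) == ["a1", "a2", "a3", "b1", "b2"]
        assert test == ["c1"]

    def test_family_overlap_always_empty(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(4, 40))
            ids = [f"p{i}" for i in range(n)]
            fams = {pid: f"F{rng.integers(1, 8)}" for pid in ids}
            n_train = int(rng.integers(1, n))
            train, test = split_by_family(ids, fams, n_train)
            assert not {fams[p] for p in train} & {fams[p] for p in test}
            assert sorted(train + test) == sorted(ids)

    def test_family_missing_labels_listed(self):
        with pytest.raises(ValueError, match="p1"):
            split_by_family(["p0", "p1"], {"p0": "A"}, 1)

    def test_plddt_even_split(self):
        high, low = split_by_plddt({"a": 90.0, "b": 70.0, "c": 50.0, "d": 30.0})
        assert high == ["a", "b"] and low == ["c", "d"]

    def test_plddt_ties_break_by_id_median_goes_high(self):
        high, low = split_by_plddt({"c": 50.0, "a": 50.0, "b": 50.0})
        assert high == ["a", "b"] and low == ["c"]

    def test_plddt_group_means_ordered(self):
        rng = np.random.default_rng(1)
        means = {f"p{i}": float(rng.uniform(30, 95)) for i in range(11)}
        high, low = split_by_plddt(means)
        assert np.mean([means[p] for p in high]) >= np.mean([means[p] for p in low])


class TestMetrics:
    def test_closed_form_from_confusion_counts(self):
        r = metrics_from_counts(tp=3, tn=4, fp=1, fn=2)
        assert r.acc == pytest.approx(0.7)
        assert r.pre == pytest.approx(0.75)
        assert r.sn == pytest.approx(0.6)
        assert r.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_predictions(self):
        r = metrics_from_counts(tp=5, tn=5, fp=0, fn=0)
        assert (r.acc, r.pre, r.sn, r.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_counts_guarded(self):
        r = metrics_from_counts(tp=0, tn=4, fp=0, fn=0)
        assert r.pre == 0.0 and r.f1 == 0.0

    def test_matches_independent_recount_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            probs = rng.random(n)
            labels = (rng.random(n) < 0.5).astype(int)
            pred = PredictionResult("p", np.arange(n), probs)
            truth = SiteSet("p", np.arange(n), labels)
            r = evaluate([pred], [truth])
            calls = (probs >= 0.5).astype(int)
            tp = int(((calls == 1) & (labels == 1)).sum())
            tn = int(((calls == 0) & (labels == 0)).sum())
            fp = int(((calls == 1) & (labels == 0)).sum())
            fn = int(((calls == 0) & (labels == 1)).sum())
            assert (r.tp, r.tn, r.fp, r.fn) == (tp, tn, fp, fn)
            assert r.f1 <= (r.pre + r.sn) / 2 + 1e-12

    def test_index_mismatch_rejected(self):
        pred = PredictionResult("p", np.array([0, 1]), np.array([0.9, 0.1]))
        truth = SiteSet("p", np.array([0]), np.array([1]))
        with pytest.raises(ValueError, match="absent"):
            evaluate([pred], [truth])


@pytest.fixture(scope="module")
def tiny_corpus():
    corpus = generate_corpus(SyntheticSpec(
        n_proteins=8, length_range=(40, 60), noise_rate=0.0, seed=2))
    return corpus_examples(corpus, seed=2)


class TestTrainingLoop:
    def test_zero_learning_rate_leaves_params_bitwise(self, tiny_corpus):
        config = ModelConfig(cnn_hidden=4, cnn_kernels=(3, 3), seed=0)
        result = train(tiny_corpus, config, epochs=1, lr=0.0, seed=0,
                       val_fraction=0.0, feature_noise=0, embedding_noise=0)
        from graphphos.model import init_params
        fresh = init_params(config, emb_dim=tiny_corpus[0].embeddings.shape[1])
        for k in fresh:
            np.testing.assert_array_equal(result.params[k].data, fresh[k].data)

    def test_seeded_training_is_bitwise_reproducible(self, tiny_corpus):
        config = ModelConfig(cnn_hidden=4, cnn_kernels=(3, 3), seed=1)
        a = train(tiny_corpus, config, epochs=3, seed=1)
        b = train(tiny_corpus, config, epochs=3, seed=1)
        assert a.loss_log == b.loss_log
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_loss_decreases_on_learnable_signal(self, tiny_corpus):
        config = ModelConfig(cnn_hidden=4, cnn_kernels=(3, 3), seed=0)
        result = train(tiny_corpus, config, epochs=30, seed=0)
        assert result.loss_log[-1] < 0.6 * result.loss_log[0]

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError, match="no training examples"):
            train([], ModelConfig(seed=0), epochs=1, seed=0)


def test_ablation_suite_identical_configs_identical_rows(tiny_corpus):
    config = ModelConfig(cnn_hidden=4, cnn_kernels=(3, 3), seed=0)
    table = run_ablation_suite(tiny_corpus[:6], tiny_corpus[6:],
                               {"a": config, "b": config}, epochs=2, seed=0)
    assert table.loc["a"].equals(table.loc["b"])
    assert {"acc", "pre", "sn", "f1"} <= set(table.columns)
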