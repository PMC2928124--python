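"""Region encoding, network training, prediction and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmdscape import GES, BitopicProtein
from tmdscape.classifier import (
    REGIONS,
    NetworkModel,
    TrainingConfig,
    confusion_stats,
    cross_validate,
    encode_dataset,
    encode_regions,
    predict,
    predict_scores,
    threshold_scan,
    train,
)
from tmdscape.scales import AMINO_ACIDS
from tmdscape.synthetic_data import DEFAULT_PRESETS, sample_dataset

from test_profiles import aligned_from_string


def separable_data(n_per_class=40, seed=0):
    """Two composition classes with disjoint support: trivially separable."""
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for cls, block in (("A", 0), ("B", 3)):
        for _ in range(n_per_class):
            v = np.zeros(120)
            v[block * 20 : block * 20 + 20] = rng.dirichlet(np.ones(20))
            X.append(v)
            labels.append(cls)
    return np.array(X), labels


class TestEncoding:
    def test_vector_length_120(self, default_aligned):
        aligned = default_aligned["fungal-er"][0][0]
        assert encode_regions(aligned).shape == (120,)

    def test_pure_region_block(self):
        aligned = aligned_from_string("AAAA" + "L" * 20)
        # positions 1-4 are all A: the second region block is 1.0 at A
        vec = encode_regions(aligned)
        block = vec[20:40]
        assert block[AMINO_ACIDS.index("A")] == 1.0
        assert block.sum() == 1.0

    def test_populated_blocks_sum_to_one(self, default_aligned):
        for aligned in default_aligned["fungal-golgi"][0][:20]:
            vec = encode_regions(aligned)
            for r in range(len(REGIONS)):
                s = vec[r * 20 : (r + 1) * 20].sum()
                assert s == pytest.approx(1.0, abs=1e-9) or s == 0.0

    def test_absent_region_is_zero_block(self):
        aligned = aligned_from_string("L" * 12)  # nothing at positions 18-24, no flank
        vec = encode_regions(aligned)
        assert np.all(vec[100:120] == 0)
        assert np.all(vec[0:20] == 0)  # no cytosolic flank either


class TestTraining:
    def test_separable_classes_learned(self):
        X, labels = separable_data()
        model = train(X, labels, seed=0)
        scores = predict_scores(model, X)
        accuracy = np.mean([model.classes[j] == l for j, l in zip(scores.argmax(1), labels)])
        assert accuracy >= 0.99

    def test_deterministic_given_seed(self):
        X, labels = separable_data()
        a = train(X, labels, seed=3)
        b = train(X, labels, seed=3)
        assert np.array_equal(a.w_in, b.w_in) and np.array_equal(a.w_out, b.w_out)

    def test_loss_nonincreasing_on_separable_data(self):
        X, labels = separable_data()
        model = train(X, labels, seed=1)
        losses = np.array(model.loss_history)
        # online updates allow sub-0.1% wobble between epoch-end evaluations
        assert np.all(np.diff(losses) <= 1e-3 * losses[:-1])
        assert losses[-1] < losses[0]

    def test_shuffled_labels_give_chance_accuracy(self, default_sets):
        """Destroying the label-feature link leaves held-out accuracy near
        the 1/C chance level."""
        rng = np.random.default_rng(0)
        sets = [ds for ds, _ in default_sets.values()]
        X, labels, _ = encode_dataset(sets, GES)
        labels = list(rng.permutation(labels))
        half = len(labels) // 2
        idx = rng.permutation(len(labels))
        tr, te = idx[:half], idx[half:]
        model = train(X[tr], [labels[i] for i in tr], seed=0)
        scores = predict_scores(model, X[te])
        accuracy = np.mean(
            [model.classes[j] == labels[i] for j, i in zip(scores.argmax(1), te)]
        )
        assert abs(accuracy - 0.25) <= 0.10

    def test_single_class_rejected(self):
        X, labels = separable_data()
        with pytest.raises(ValueError):
            train(X, ["A"] * len(labels), seed=0)

    def test_model_json_round_trip(self):
        X, labels = separable_data(10)
        model = train(X, labels, seed=0)
        back = NetworkModel.from_json(model.to_json())
        assert np.allclose(back.w_in, model.w_in)
        assert back.classes == model.classes
        assert np.allclose(predict_scores(back, X), predict_scores(model, X))


class TestPredict:
    def test_reverse_flag_on_palindrome_is_identity(self, default_sets):
        sets = [ds for ds, _ in default_sets.values()]
        X, labels, _ = encode_dataset(sets, GES)
        model = train(X, labels, seed=0)
        seq = "NQSG" + "LIVFA" + "LL" + "AFVIL" + "GSQN"
        p = BitopicProtein("pal", seq, "II", "ER", (5, 16))
        forward, _ = predict(model, p, GES, reverse=False)
        backward, _ = predict(model, p, GES, reverse=True)
        for cls in forward:
            assert forward[cls] == pytest.approx(backward[cls], abs=1e-12)

    def test_reversed_pm_scores_degrade(self, default_sets):
        """Reversing PM-like sequences flips their leaflet asymmetry, so the
        trained network's PM score drops on average."""
        sets = [ds for ds, _ in default_sets.values()]
        X, labels, _ = encode_dataset(sets, GES)
        model = train(X, labels, seed=0)
        pm = default_sets["fungal-pm"][0]
        fwd, rev = [], []
        for protein in pm.proteins[:60]:
            try:
                fwd.append(predict(model, protein, GES, reverse=False)[0]["PM"])
                rev.append(predict(model, protein, GES, reverse=True)[0]["PM"])
            except Exception:
                continue
        assert np.mean(rev) < np.mean(fwd)


class TestConfusionStats:
    def test_perfect_prediction(self):
        s = confusion_stats(5, 5, 0, 0)
        assert s.mcc == 1.0 and s.sensitivity == 1.0 and s.specificity == 1.0

    def test_hand_case(self):
        s = confusion_stats(3, 4, 1, 2)
        assert s.mcc == pytest.approx(10 / np.sqrt(600))
        assert s.sensitivity == pytest.approx(3 / 5)
        assert s.specificity == pytest.approx(3 / 4)

    def test_zero_sensitivity(self):
        assert confusion_stats(0, 5, 0, 5).sensitivity == 0.0

    def test_degenerate_denominator_gives_zero_mcc(self):
        assert confusion_stats(3, 0, 0, 0).mcc == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_stats(0, 0, 0, 0)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_mcc_invariant_under_tp_tn_swap(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        a = confusion_stats(tp, tn, fp, fn).mcc
        b = confusion_stats(tn, tp, fn, fp).mcc
        assert a == pytest.approx(b)


class TestThresholdScan:
    def test_perfectly_separated(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1], dtype=bool)
        best, curve = threshold_scan(scores, labels)
        assert 0.2 < best <= 0.8
        assert curve[:, 1].max() == 1.0

    def test_constant_scores_flat_zero(self):
        scores = np.full(10, 0.5)
        labels = np.array([0, 1] * 5, dtype=bool)
        _, curve = threshold_scan(scores, labels)
        assert np.allclose(curve[:, 1], 0.0)

    def test_matches_dense_grid_oracle(self, rng):
        """Best threshold agrees with an exhaustive fine-grid search to
        within 0.02 (in MCC-equivalent terms)."""
        scores = np.concatenate([rng.beta(2, 5, 300), rng.beta(5, 2, 300)])
        labels = np.concatenate([np.zeros(300, bool), np.ones(300, bool)])
        best, curve = threshold_scan(scores, labels)

        def mcc_at(t):
            tp = np.sum((scores >= t) & labels)
            fp = np.sum((scores >= t) & ~labels)
            fn = np.sum((scores < t) & labels)
            tn = np.sum((scores < t) & ~labels)
            d = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
            return (tp * tn - fp * fn) / np.sqrt(d) if d else 0.0

        dense = np.arange(0, 1.0001, 0.001)
        oracle_best = dense[np.argmax([mcc_at(t) for t in dense])]
        assert mcc_at(best) >= mcc_at(oracle_best) - 0.02


class TestCrossValidation:
    def test_perfect_separation(self):
        X, labels = separable_data(40)
        # wrap into fake datasets via direct train/test: use the lower-level
        # API through cross_validate on synthetic organelle sets is covered
        # below; here check the separable bound via a manual 5-fold
        from tmdscape.classifier import _stratified_folds

        rng = np.random.default_rng(0)
        folds = _stratified_folds(labels, 5, rng)
        correct = 0
        for fold in folds:
            mask = np.zeros(len(labels), bool)
            mask[fold] = True
            model = train(X[~mask], [labels[i] for i in np.flatnonzero(~mask)], seed=rng)
            scores = predict_scores(model, X[mask])
            correct += sum(
                model.classes[j] == labels[i]
                for j, i in zip(scores.argmax(1), np.flatnonzero(mask))
            )
        assert correct / len(labels) == 1.0

    def test_folds_partition_data(self):
        from tmdscape.classifier import _stratified_folds

        labels = ["A"] * 23 + ["B"] * 31 + ["C"] * 17
        folds = _stratified_folds(labels, 5, np.random.default_rng(0))
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(len(labels)))

    def test_small_class_rejected(self):
        from tmdscape.classifier import _stratified_folds

        with pytest.raises(ValueError):
            _stratified_folds(["A"] * 10 + ["B"] * 3, 5, np.random.default_rng(0))

    def test_relabeling_symmetry(self, default_sets):
        """Renaming every organelle label leaves mean accuracy unchanged."""
        from tmdscape.proteins import BitopicProtein, OrganelleDataset

        sets = [ds for ds, _ in list(default_sets.values())[:2]]
        renamed = []
        for ds in sets:
            new = "X" + ds.organelle
            renamed.append(
                OrganelleDataset(
                    new,
                    [
                        BitopicProtein(p.id, p.sequence, p.topology, new, p.guide_tmd,
                                       p.species_tag)
                        for p in ds
                    ],
                )
            )
        a = cross_validate(sets, k=5, seed=9)
        b = cross_validate(renamed, k=5, seed=9)
        assert a.accuracy == pytest.approx(b.accuracy)
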