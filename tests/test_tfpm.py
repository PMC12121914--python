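import numpy as np
import pytest

from methylpref.io import LabeledDataset, ProteinRecord
from methylpref.raac import feature_matrix, load_scheme
from methylpref.simulate import SyntheticSpec, generate
from methylpref.tfpm import (
    HyperParams,
    TfpmModel,
    TfpmResults,
    TrainingError,
    platt_fit,
    platt_prob,
)


def nearest_centroid_accuracy(dataset, scheme, k=1):
    """Independent separability oracle: classify by nearer class centroid."""
    X = feature_matrix(dataset.records, scheme, k)
    y = dataset.labels
    c1, c0 = X[y == 1].mean(axis=0), X[y == 0].mean(axis=0)
    pred = (np.linalg.norm(X - c1, axis=1) < np.linalg.norm(X - c0, axis=1)).astype(int)
    return (pred == y).mean()


class TestHyperParams:
    def test_defaults_are_grid_optimum(self):
        hp = HyperParams()
        assert hp.as_tuple() == (11, 1, 0.01, 1.0)

    @pytest.mark.parametrize("kw", [{"k": 0}, {"C": 0}, {"gamma": -1}])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            HyperParams(**kw)


class TestFit:
    def test_separable_classes_learned_perfectly(self, separable_dataset, op11):
        # verify separability with an independent nearest-centroid oracle first
        assert nearest_centroid_accuracy(separable_dataset, op11) == 1.0
        hp = HyperParams(op=11, k=1, C=1.0, gamma=1.0)
        res = TfpmModel(separable_dataset, hp).fit(seed=0)
        preds = res.predict(separable_dataset.records)
        assert [p.label for p in preds] == separable_dataset.labels.tolist()

    def test_single_class_raises(self):
        ds = LabeledDataset(
            records=[ProteinRecord("a", "MKV"), ProteinRecord("b", "MKW")],
            labels=np.array([1, 1]),
        )
        with pytest.raises(TrainingError):
            TfpmModel(ds).fit()

    def test_determinism(self, separable_dataset):
        r1 = TfpmModel(separable_dataset).fit(seed=3)
        r2 = TfpmModel(separable_dataset).fit(seed=3)
        assert r1.training_checksum == r2.training_checksum
        assert r1.platt == r2.platt
        p1 = r1.predict(separable_dataset.records)
        p2 = r2.predict(separable_dataset.records)
        assert p1 == p2

    def test_feature_dimension_recorded(self, separable_dataset):
        res = TfpmModel(separable_dataset, HyperParams(op=11, k=2, C=1, gamma=1)).fit()
        assert res.feature_dimension == 121


class TestPredict:
    @pytest.fixture()
    def fitted(self, separable_dataset):
        return TfpmModel(separable_dataset, HyperParams(op=11, k=1, C=1, gamma=1)).fit()

    def test_empty_input(self, fitted):
        assert fitted.predict([]) == []

    def test_threshold_consistency(self, fitted, separable_dataset):
        preds = fitted.predict(separable_dataset.records)
        assert all((p.probability >= 0.5) == bool(p.label) for p in preds)

    def test_identical_sequences_identical_predictions(self, fitted):
        recs = [ProteinRecord("x1", "MKVEQRKEQRK"), ProteinRecord("x2", "MKVEQRKEQRK")]
        p1, p2 = fitted.predict(recs)
        assert p1.probability == p2.probability
        assert p1.score == p2.score

    def test_lenient_flags_short_sequence(self, fitted):
        # too short to featurize at k=1 after stripping non-canonical residues
        preds = fitted.predict([ProteinRecord("odd", "XXB")], lenient=True)
        assert preds[0].flagged and preds[0].label == 0

    def test_strict_mode_raises_on_noncanonical(self, fitted):
        from methylpref.io import ValidationError

        with pytest.raises(ValidationError):
            fitted.predict([ProteinRecord("odd", "ACB")], lenient=False)


class TestCrossValidate:
    def test_separable_pooled_accuracy_one(self, separable_dataset):
        pooled, folds = TfpmModel(
            separable_dataset, HyperParams(op=11, k=1, C=1, gamma=1)
        ).cross_validate(folds=5, seed=0)
        assert pooled.accuracy == 1.0
        assert len(folds) == 5

    def test_folds_one_rejected(self, separable_dataset):
        with pytest.raises(ValueError):
            TfpmModel(separable_dataset).cross_validate(folds=1)

    def test_class_too_small_for_stratification(self):
        ds = LabeledDataset(
            records=[ProteinRecord(f"p{i}", "MKVLEQRK") for i in range(6)],
            labels=np.array([1, 1, 1, 1, 1, 0]),
        )
        with pytest.raises(TrainingError, match="stratify"):
            TfpmModel(ds).cross_validate(folds=5)

    def test_permuted_labels_accuracy_near_majority_rate(self):
        """Held-out accuracy on label-permuted data ~ majority-class rate."""
        rng = np.random.default_rng(5)
        accs = []
        for s in range(6):
            ds = generate(SyntheticSpec(n_pos=40, n_neg=40, delta=0.3, seed=s))
            perm = rng.permutation(len(ds))
            ds_null = LabeledDataset(
                records=ds.records, labels=ds.labels[perm]
            )
            pooled, _ = TfpmModel(ds_null, HyperParams(C=1.0)).cross_validate(
                folds=4, seed=s
            )
            accs.append(pooled.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.12


@pytest.fixture(scope="module")
def composition_dataset():
    # signal lives purely in single-symbol composition
    return generate(SyntheticSpec(n_pos=40, n_neg=40, delta=0.25, seed=11))


@pytest.fixture(scope="module")
def ranker_fitted():
    ds = generate(SyntheticSpec(n_pos=60, n_neg=60, delta=0.25, seed=3))
    return TfpmModel(ds, HyperParams(C=1.0)).fit()


class TestGridSearch:
    def test_singleton_grid(self, composition_dataset):
        res = TfpmModel(composition_dataset).grid_search(
            ops=[11], ks=[1], Cs=[0.01], gammas=[1.0], folds=3, seed=0
        )
        assert res.best.as_tuple() == (11, 1, 0.01, 1.0)
        assert len(res.table) == 1

    def test_composition_signal_selects_k1(self, composition_dataset):
        res = TfpmModel(composition_dataset).grid_search(
            ops=[11], ks=[1, 2, 3], Cs=[1.0], gammas=[1.0], folds=3, seed=0
        )
        assert res.best.k == 1

    def test_empty_grid_rejected(self, composition_dataset):
        with pytest.raises(ValueError, match="empty"):
            TfpmModel(composition_dataset).grid_search(ops=[], ks=[], Cs=[], gammas=[])

    def test_tie_break_lexicographic(self, separable_dataset):
        # Perfectly separable data gives AUC=1 everywhere; first combo wins.
        res = TfpmModel(separable_dataset).grid_search(
            ops=[11], ks=[1], Cs=[1.0, 10.0], gammas=[1.0], folds=3, seed=0
        )
        assert res.best_cv_auc == 1.0
        assert res.best.C == 1.0

    def test_table_columns(self, composition_dataset):
        res = TfpmModel(composition_dataset).grid_search(
            ops=[11], ks=[1], Cs=[0.01], gammas=[1.0], folds=3, seed=0
        )
        assert {"op", "k", "C", "gamma", "cv_auc"} <= set(res.table.columns)


class TestRankProteome:
    def test_sorted_descending_with_rank_column(self, ranker_fitted):
        proteome = generate(SyntheticSpec(n_pos=15, n_neg=15, delta=0.25, seed=9)).records
        table = ranker_fitted.rank_proteome(proteome, top_n=10)
        assert len(table) == 30  # full table persisted
        assert table.attrs["top_n"] == 10
        probs = table["probability"].to_numpy()
        assert (np.diff(probs) <= 0).all()
        assert table["rank"].tolist() == list(range(1, 31))

    def test_identical_sequences_adjacent(self, ranker_fitted):
        recs = [
            ProteinRecord("b_twin", "MKVEQRKEQRKAAA"),
            ProteinRecord("zzz", "GPGPGPSTSTMKV"),
            ProteinRecord("a_twin", "MKVEQRKEQRKAAA"),
        ]
        table = ranker_fitted.rank_proteome(recs, top_n=3)
        twins = table[table["id"].str.endswith("twin")]
        assert abs(twins.index[0] - twins.index[1]) == 1
        # ties broken by id ascending
        assert twins["id"].tolist() == ["a_twin", "b_twin"]

    def test_top_n_larger_than_proteome(self, ranker_fitted):
        recs = [ProteinRecord("a", "MKVEQRK"), ProteinRecord("b", "GPGPSTS")]
        table = ranker_fitted.rank_proteome(recs, top_n=50)
        assert table.attrs["top_n"] == 2

    def test_invalid_top_n(self, ranker_fitted):
        with pytest.raises(ValueError):
            ranker_fitted.rank_proteome([ProteinRecord("a", "MKV")], top_n=0)

    def test_empty_proteome(self, ranker_fitted):
        with pytest.raises(ValueError):
            ranker_fitted.rank_proteome([], top_n=5)


class TestSerialization:
    def test_round_trip(self, tmp_path, separable_dataset):
        res = TfpmModel(separable_dataset).fit(seed=1)
        path = tmp_path / "model.pkl"
        res.save(path)
        back = TfpmResults.load(path)
        assert back.hyperparams == res.hyperparams
        assert back.platt == res.platt
        assert back.scheme.mapping() == res.scheme.mapping()
        p1 = res.predict(separable_dataset.records)
        p2 = back.predict(separable_dataset.records)
        assert p1 == p2

    def test_summary_mentions_key_facts(self, separable_dataset):
        res = TfpmModel(separable_dataset).fit()
        text = res.summary()
        assert "Op11" in text and "support vectors" in text


class TestPlatt:
    def test_probabilities_monotone_in_score(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(-1, 1, 50)])
        labels = np.concatenate([np.ones(50, int), np.zeros(50, int)])
        A, B = platt_fit(scores, labels)
        grid = np.linspace(-3, 3, 21)
        probs = platt_prob(grid, A, B)
        assert (np.diff(probs) > 0).all()
        assert 0.2 < platt_prob(np.array([0.0]), A, B)[0] < 0.8

    def test_recovers_known_sigmoid(self):
        # labels generated from a known sigmoid of the score
        rng = np.random.default_rng(42)
        f = rng.uniform(-4, 4, 4000)
        p_true = 1 / (1 + np.exp(-2.0 * f))  # A=-2, B=0
        y = (rng.uniform(size=f.size) < p_true).astype(int)
        A, B = platt_fit(f, y)
        assert A == pytest.approx(-2.0, abs=0.25)
        assert B == pytest.approx(0.0, abs=0.2)
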