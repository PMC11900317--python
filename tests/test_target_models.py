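import numpy as np
import pytest

from kinasepred.curation import RawActivityRecord, standardize_structure
from kinasepred.family_model import ModelSpec, TrainedModel, classify
from kinasepred.featurize import FeatureMatrix
from kinasepred.fixtures import FixtureSpec, generate_target_fixture
from kinasepred.metrics import compute_metrics, summarize_repeats
from kinasepred.target_models import (
    TargetDataset,
    TargetModelCard,
    binarize_inhibition,
    build_target_datasets,
    ensemble_report,
    predict_panel,
    score_panel,
    train_target_model,
)


def _curated(smiles_list):
    out = []
    for i, s in enumerate(smiles_list):
        rec = standardize_structure(s, f"c{i}")
        assert rec.kept
        out.append(rec)
    return out


def _act(smiles, target, value, conf=9, cid="a", atype="IC50"):
    return RawActivityRecord(cid, smiles, target, atype, value, conf)


class TestBuildTargetDatasets:
    def test_ten_micromolar_rule(self):
        curated = _curated(["CCCCCCCCCCCCCCCC", "CCCCCCCCCCCCCCCCC"])
        acts = [
            _act(curated[0].smiles_std, "T1", 9_000.0),
            _act(curated[1].smiles_std, "T1", 10_001.0),
        ]
        datasets, _ = build_target_datasets(acts, curated, min_n=1)
        (ds,) = datasets
        labels = {rec.smiles_std: lab for rec, lab in ds.records}
        assert labels[curated[0].smiles_std] == "active"
        assert labels[curated[1].smiles_std] == "inactive"

    def test_most_potent_record_decides(self):
        curated = _curated(["CCCCCCCCCCCCCCCC"])
        smi = curated[0].smiles_std
        acts = [_act(smi, "T1", 50_000.0), _act(smi, "T1", 500.0, atype="Ki")]
        datasets, _ = build_target_datasets(acts, curated, min_n=1)
        assert datasets[0].records[0][1] == "active"

    def test_low_confidence_dropped(self):
        curated = _curated(["CCCCCCCCCCCCCCCC"])
        acts = [_act(curated[0].smiles_std, "T1", 100.0, conf=8)]
        datasets, skipped = build_target_datasets(acts, curated, min_n=1)
        assert not datasets

    def test_min_n_boundary(self):
        curated = _curated(["CCCCCCC" + "C" * i for i in range(8, 107)])  # 99 mols
        acts = [_act(m.smiles_std, "T1", 100.0, cid=m.compound_id) for m in curated]
        datasets, skipped = build_target_datasets(acts, curated, min_n=100)
        assert datasets == []
        assert skipped == {"T1": 99}
        datasets, skipped = build_target_datasets(acts, curated, min_n=99)
        assert len(datasets) == 1 and not skipped

    def test_counts_conserved(self):
        curated = _curated(["CCCCCCC" + "C" * i for i in range(8, 28)])
        acts = [
            _act(m.smiles_std, "T1", 100.0 if i % 3 else 20_000.0, cid=f"c{i}")
            for i, m in enumerate(curated)
        ]
        (ds,), _ = build_target_datasets(acts, curated, min_n=1)
        assert ds.n_active + ds.n_inactive == len(ds.records)


class TestInactiveRatio:
    def _card(self, n_active, n_inactive, ratio=None):
        summary = summarize_repeats([compute_metrics(5, 1, 5, 1)])
        spec = ModelSpec.make("random_forest", "morgan", {}, seed=0)
        model = TrainedModel(spec=spec, estimator=object())
        return TargetModelCard(
            target_id="T",
            n_active=n_active,
            n_inactive=n_inactive,
            inactive_ratio=ratio if ratio is not None else n_inactive / n_active,
            cv_summary=summary,
            model=model,
        )

    def test_ratio_exactly_quarter_not_flagged(self):
        assert not self._card(80, 20).imbalance_flag  # ratio 0.25

    def test_ratio_just_below_flagged(self):
        assert self._card(80, 20, ratio=0.2499999).imbalance_flag

    def test_dataset_ratio(self):
        curated = _curated(["CCCCCCC" + "C" * i for i in range(8, 18)])
        records = [(m, "active" if i < 8 else "inactive") for i, m in enumerate(curated)]
        ds = TargetDataset(target_id="T", records=records)
        assert ds.inactive_ratio == pytest.approx(0.25)


class _StubEstimator:
    """predict_proba returns a fixed positive-class column."""

    classes_ = np.array([0, 1])

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        p = self.probs[: len(X)]
        return np.column_stack([1 - p, p])


def _stub_model(probs, threshold=0.75):
    spec = ModelSpec.make("random_forest", "morgan", {}, seed=0)
    return TrainedModel(
        spec=spec, estimator=_StubEstimator(probs), decision_threshold=threshold
    )


class TestDecisionThreshold:
    def test_boundary_exact(self):
        model = _stub_model([0.75, 0.749, 0.7499999, 1.0, 0.0])
        fm = FeatureMatrix(
            compound_ids=[str(i) for i in range(5)],
            kind="morgan",
            matrix=np.zeros((5, 2048), dtype=np.uint8),
        )
        assert classify(model, fm).tolist() == [1, 0, 0, 1, 0]

    def test_threshold_monotonicity(self, rng):
        probs = rng.uniform(size=50)
        fm = FeatureMatrix(
            compound_ids=[str(i) for i in range(50)],
            kind="morgan",
            matrix=np.zeros((50, 2048), dtype=np.uint8),
        )
        counts = [
            classify(_stub_model(probs, threshold=t), fm).sum()
            for t in (0.1, 0.25, 0.5, 0.75, 0.9, 1.01)
        ]
        assert counts == sorted(counts, reverse=True)


@pytest.fixture(scope="module")
def trained_card():
    acts = generate_target_fixture(
        1, [FixtureSpec(n_active=60, n_inactive=60, seed=31)]
    )
    curated = _curated(sorted({a.smiles for a in acts}))
    (ds,), _ = build_target_datasets(acts, curated, min_n=100)
    return train_target_model(ds, seed=0, n_repeats=2), ds


class TestTrainTargetModel:
    def test_separable_fixture_high_mcc(self, trained_card):
        card, _ = trained_card
        assert card.cv_summary.mean["mcc"] >= 0.9

    def test_card_fields(self, trained_card):
        card, ds = trained_card
        assert card.n_active == ds.n_active
        assert card.decision_threshold == 0.75
        assert not card.imbalance_flag

    def test_determinism(self, trained_card):
        card, ds = trained_card
        again = train_target_model(ds, seed=0, n_repeats=2)
        assert again.cv_summary.mean == card.cv_summary.mean

    def test_single_class_rejected(self):
        curated = _curated(["CCCCCCC" + "C" * i for i in range(8, 13)])
        ds = TargetDataset("T", [(m, "active") for m in curated])
        with pytest.raises(ValueError, match="single-class"):
            train_target_model(ds)


class TestEnsembleReport:
    def _card_with_metrics(self, cm, flagged):
        spec = ModelSpec.make("random_forest", "morgan", {}, seed=0)
        return TargetModelCard(
            target_id="T",
            n_active=100,
            n_inactive=10 if flagged else 100,
            inactive_ratio=0.1 if flagged else 1.0,
            cv_summary=summarize_repeats([cm]),
            model=TrainedModel(spec=spec, estimator=object()),
        )

    def test_single_card(self):
        cm = compute_metrics(50, 5, 45, 10)
        report = ensemble_report([self._card_with_metrics(cm, False)])
        assert report["all"]["mcc"]["mean"] == pytest.approx(cm.mcc)

    def test_no_flags_identical(self):
        cards = [
            self._card_with_metrics(compute_metrics(50, 5, 45, 10), False),
            self._card_with_metrics(compute_metrics(40, 8, 42, 12), False),
        ]
        report = ensemble_report(cards, exclude_flagged=True)
        assert report["all"] == report["filtered"]

    def test_flag_filtering_direction(self):
        # flagged cards: strong on actives, poor NPV / specificity
        good = compute_metrics(90, 5, 95, 10)
        bad = compute_metrics(95, 40, 10, 20)
        cards = [self._card_with_metrics(good, False) for _ in range(3)] + [
            self._card_with_metrics(bad, True) for _ in range(3)
        ]
        report = ensemble_report(cards, exclude_flagged=True)
        assert report["filtered"]["npv"]["mean"] > report["all"]["npv"]["mean"]
        assert (
            report["filtered"]["specificity"]["mean"]
            > report["all"]["specificity"]["mean"]
        )

    def test_all_flagged_rejected(self):
        cards = [self._card_with_metrics(compute_metrics(9, 4, 1, 2), True)]
        with pytest.raises(ValueError):
            ensemble_report(cards, exclude_flagged=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_report([])


class TestPanel:
    def test_shape_and_scoring(self, trained_card):
        card, ds = trained_card
        compounds = [rec for rec, _ in ds.records[:8]]
        cards = [card] * 3
        experimental = np.zeros((8, 3), dtype=int)
        panel = predict_panel(cards, compounds, experimental=experimental)
        assert panel.predicted.shape == (8, 3)
        rates = score_panel(panel)
        assert set(rates) == {c.compound_id for c in compounds}
        for v in rates.values():
            assert 0.0 <= v <= 100.0

    def test_empty_compound_list(self, trained_card):
        card, _ = trained_card
        panel = predict_panel([card], [])
        assert panel.predicted.shape == (0, 1)

    def test_success_rate_arithmetic(self):
        panel_pred = np.zeros((1, 20), dtype=int)
        panel_exp = np.zeros((1, 20), dtype=int)
        panel_pred[0, :5] = 1  # 5 disagreements -> 15/20 correct
        from kinasepred.target_models import PanelMatrix

        panel = PanelMatrix(
            compound_ids=["VS2"],
            target_ids=[f"T{i}" for i in range(20)],
            predicted=panel_pred,
            experimental=panel_exp,
        )
        assert score_panel(panel)["VS2"] == 75.0

    def test_unfitted_model_rejected(self):
        spec = ModelSpec.make("random_forest", "morgan", {}, seed=0)
        card = TargetModelCard(
            target_id="T",
            n_active=1,
            n_inactive=1,
            inactive_ratio=1.0,
            cv_summary=summarize_repeats([compute_metrics(1, 0, 1, 0)]),
            model=TrainedModel(spec=spec, estimator=object()),
        )
        with pytest.raises(ValueError, match="not fitted"):
            predict_panel([card], [])


def test_binarize_inhibition_at_50():
    out = binarize_inhibition(np.array([49.9, 50.0, 100.0, 0.0]))
    assert out.tolist() == [0, 1, 1, 0]
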