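import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from chromae.evaluation import (
    BAE,
    MAE,
    ConfusionMatrix,
    confusion,
    metrics,
)


def kappa_oracle(tp, fp, fn, tn):
    """Cohen's kappa from first principles (agreement vs chance)."""
    n = tp + fp + fn + tn
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    return (p_o - p_e) / (1 - p_e) if p_e != 1 else 0.0


class TestConfusion:
    truth = {f"g{i}": (MAE if i < 3 else BAE) for i in range(10)}

    def test_perfect_agreement(self):
        cm = confusion(self.truth, dict(self.truth))
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 7, 0, 0)

    def test_constant_bae_predictor(self):
        preds = {g: BAE for g in self.truth}
        cm = confusion(self.truth, preds)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (0, 3, 7, 0)

    def test_order_invariance(self):
        preds = {g: MAE for g in self.truth}
        shuffled = dict(reversed(list(self.truth.items())))
        assert confusion(self.truth, preds) == confusion(shuffled, preds)

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError, match="no genes shared"):
            confusion(self.truth, {"other": MAE})

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError, match="g0"):
            confusion({"g0": "weird"}, {"g0": MAE})


class TestMetrics:
    def test_worked_example(self):
        # 1000 genes, 100 true MAE, half of MAE calls correct
        pm = metrics(ConfusionMatrix(tp=50, fp=50, fn=50, tn=850))
        assert pm.precision == pytest.approx(0.5)
        assert pm.recall == pytest.approx(0.5)
        assert pm.f1 == pytest.approx(0.5)
        assert pm.accuracy == pytest.approx(0.9)
        assert pm.kappa == pytest.approx((0.9 - 0.82) / (1 - 0.82), abs=1e-9)

    def test_perfect_matrix(self):
        pm = metrics(ConfusionMatrix(tp=3, fp=0, fn=0, tn=7))
        assert (pm.precision, pm.recall, pm.f1, pm.kappa, pm.accuracy) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_undefined_precision_is_none_not_zero(self):
        pm = metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert pm.precision is None
        assert pm.f1 is None
        assert pm.recall == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=1)
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, fp=0, fn=0, tn=0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200),
            st.integers(0, 200), st.integers(0, 200),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_metric_algebra(self, counts):
        tp, fp, fn, tn = counts
        pm = metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        # kappa never exceeds accuracy (chance correction only lowers it)
        assert pm.kappa <= pm.accuracy + 1e-12
        assert pm.kappa == pytest.approx(kappa_oracle(tp, fp, fn, tn),
                                         abs=1e-12)
        if pm.precision is not None and pm.recall is not None and pm.f1 is not None:
            harmonic = 2 * pm.precision * pm.recall / (pm.precision + pm.recall)
            assert pm.f1 == pytest.approx(harmonic, abs=1e-12)
            assert min(pm.precision, pm.recall) - 1e-12 <= pm.f1
            assert pm.f1 <= max(pm.precision, pm.recall) + 1e-12

    def test_kappa_matches_sklearn_on_random_labelings(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 200
            truth = rng.choice([MAE, BAE], size=n, p=[0.15, 0.85])
            pred = rng.choice([MAE, BAE], size=n, p=[0.2, 0.8])
            cm = confusion(
                {str(i): truth[i] for i in range(n)},
                {str(i): pred[i] for i in range(n)},
            )
            assert metrics(cm).kappa == pytest.approx(
                cohen_kappa_score(truth, pred), abs=1e-12
            )

    def test_independent_predictor_kappa_near_zero(self):
        # random calls independent of truth: kappa -> 0 as n grows
        rng = np.random.default_rng(5)
        n = 20000
        truth = rng.choice([MAE, BAE], size=n, p=[0.1, 0.9])
        pred = rng.choice([MAE, BAE], size=n, p=[0.1, 0.9])
        cm = confusion(
            {str(i): truth[i] for i in range(n)},
            {str(i): pred[i] for i in range(n)},
        )
        assert abs(metrics(cm).kappa) < 3 / np.sqrt(n)


class TestEvaluateOnTestset:
    def test_holdout_f1_tracks_cv_f1(self, small_cfg, small_design,
                                     tmp_path):
        """A held-out set drawn from the same generating conditions scores
        close to the CV estimate (no large generalization gap)."""
        from dataclasses import replace

        from chromae.annotation import read_annotation
        from chromae.coverage import open_track
        from chromae.enrichment import build_enrichment_table
        from chromae.evaluation import evaluate_on_testset
        from chromae.simulate import generate_dataset
        from chromae.training import (
            default_registry, read_labels, train_all,
        )

        X, y = small_design
        (model,), _ = train_all(
            X, y, default_registry().subset(["glm"]), folds=5, seed=4
        )

        holdout_cfg = replace(small_cfg, seed=small_cfg.seed + 1)
        generate_dataset(holdout_cfg, tmp_path)
        genes = [g for g in read_annotation(tmp_path / "genes.bed", "bed")
                 if g.chrom != "chrX"]
        tracks = {m: open_track(tmp_path / f"{m}.bedgraph")
                  for m in ("H3K36me3", "H3K27me3")}
        control = open_track(tmp_path / "control.bedgraph")
        table, _ = build_enrichment_table(tracks, control, genes)
        truth = read_labels(tmp_path / "labels.tsv")

        pm, cm, prevalence = evaluate_on_testset(model, table, truth)
        assert cm.total == len(table)
        assert 0.0 < prevalence < 0.25
        assert pm.f1 == pytest.approx(model.cv_metrics.f1, abs=0.1)

    def test_disjoint_truth_errors(self, small_design):
        from chromae.evaluation import evaluate_on_testset
        from chromae.training import default_registry, train_all

        X, y = small_design
        (model,), _ = train_all(
            X, y, default_registry().subset(["rpart"]), folds=5, seed=4
        )
        with pytest.raises(ValueError, match="no genes shared"):
            evaluate_on_testset(model, X, {"nope": MAE})
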