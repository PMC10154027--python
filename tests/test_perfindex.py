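"""AUROC/R², the performance-index rescaling and the CV harness."""

import numpy as np
import pandas as pd
import pytest

from metapom.perfindex import (
    EvalDataset,
    EvalProtocol,
    auroc,
    evaluate_dataset,
    neural_distance_index,
    r_squared,
    read_eval_dataset,
    representation_delta,
    to_performance_index,
)
from metapom.representations import RepresentationTable
from metapom.synthetic import make_eval_dataset


def pair_counting_auroc(labels, scores):
    """Oracle: fraction of (positive, negative) pairs ordered correctly, ties 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = correct = 0
    for p in pos:
        for q in neg:
            total += 1
            correct += 1.0 if p > q else (0.5 if p == q else 0.0)
    return correct / total


def random_rep(rng, keys, width=16, name="feat"):
    return RepresentationTable(name, "correlation_centered", {k: rng.normal(size=width) for k in keys})


class TestAuroc:
    def test_perfect_and_reversed(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auroc([1, 0], [0.2, 0.9]) == 0.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=30), 1)  # rounding forces ties
        assert auroc(labels, scores) == pytest.approx(pair_counting_auroc(labels, scores))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(20):
            labels = np.r_[np.ones(100, int), np.zeros(100, int)]
            vals.append(auroc(labels, rng.normal(size=200)))
        assert abs(np.mean(vals) - 0.5) < 0.1


class TestRSquared:
    def test_exact_cases(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0
        assert r_squared(y, np.array([1.0, 2.0, 5.0])) == pytest.approx(-1.0)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.arange(5.0))


class TestPerformanceIndex:
    def test_anchor_points(self):
        assert to_performance_index(0.5, "classification") == 0.0
        assert to_performance_index(1.0, "classification") == 100.0
        assert to_performance_index(1.0, "regression") == 100.0
        assert to_performance_index(0.87, "regression") == pytest.approx(87.0)

    def test_out_of_range_auroc(self):
        with pytest.raises(ValueError):
            to_performance_index(1.2, "classification")

    def test_linear_map(self):
        xs = np.linspace(0, 1, 7)
        ys = [to_performance_index(x, "classification") for x in xs]
        assert np.allclose(np.diff(ys), np.diff(ys)[0])


class TestProtocol:
    def test_auto_split_threshold(self):
        proto = EvalProtocol()
        assert proto.resolve_split(200) == "loo"
        assert proto.resolve_split(201) == "fivefold"

    def test_resample_pairing(self):
        proto = EvalProtocol()
        assert proto.resolve_resample("loo") == "jackknife"
        assert proto.resolve_resample("fivefold") == "bootstrap"


class TestEvaluateDataset:
    def test_learnable_dataset_high_index(self):
        rng = np.random.default_rng(0)
        keys = [f"k{i}" for i in range(60)]
        table = random_rep(rng, keys)
        ds = make_eval_dataset(60, informative=True, task="classification", table=table, seed=0)
        res = evaluate_dataset(ds, table, EvalProtocol(n_seeds=2), base_seed=0)
        assert res.index >= 90

    def test_uninformative_near_zero(self):
        rng = np.random.default_rng(1)
        keys = [f"k{i}" for i in range(60)]
        table = random_rep(rng, keys)
        ds = make_eval_dataset(60, informative=False, task="classification", table=table, seed=1)
        res = evaluate_dataset(ds, table, EvalProtocol(n_seeds=3), base_seed=0)
        assert abs(res.index) < 15

    def test_regression_task(self):
        rng = np.random.default_rng(2)
        keys = [f"k{i}" for i in range(50)]
        table = random_rep(rng, keys)
        ds = make_eval_dataset(50, informative=True, task="regression", table=table, seed=2)
        res = evaluate_dataset(ds, table, EvalProtocol(n_seeds=2), base_seed=0)
        assert res.index >= 80
        assert set(res.raw_metric) == {"target"}

    def test_bit_reproducible(self):
        rng = np.random.default_rng(3)
        keys = [f"k{i}" for i in range(30)]
        table = random_rep(rng, keys)
        ds = make_eval_dataset(30, informative=True, task="classification", table=table, seed=3)
        a = evaluate_dataset(ds, table, EvalProtocol(n_seeds=2), base_seed=5)
        b = evaluate_dataset(ds, table, EvalProtocol(n_seeds=2), base_seed=5)
        assert a.index == b.index
        assert np.array_equal(a.per_seed_indices, b.per_seed_indices)

    def test_fivefold_minimum_size(self):
        rng = np.random.default_rng(4)
        keys = [f"k{i}" for i in range(4)]
        table = random_rep(rng, keys)
        ds = EvalDataset("tiny", keys, pd.DataFrame({"t": [0, 1, 0, 1]}), "classification")
        with pytest.raises(ValueError):
            evaluate_dataset(ds, table, EvalProtocol(split="fivefold", n_seeds=1))


class TestRepresentationDelta:
    def test_self_delta_zero(self):
        rng = np.random.default_rng(5)
        keys = [f"k{i}" for i in range(30)]
        table = random_rep(rng, keys)
        ds = make_eval_dataset(30, informative=True, task="classification", table=table, seed=5)
        res = evaluate_dataset(ds, table, EvalProtocol(n_seeds=2), base_seed=1)
        delta, sd = representation_delta(res, res)
        assert delta == 0.0 and sd == 0.0

    def test_informative_beats_scrambled(self):
        rng = np.random.default_rng(6)
        keys = [f"k{i}" for i in range(40)]
        table = random_rep(rng, keys)
        ds = make_eval_dataset(40, informative=True, task="classification", table=table, seed=6)
        scrambled_keys = list(rng.permutation(keys))
        scrambled = RepresentationTable(
            "scrambled", table.metric, {k: table.vectors[s] for k, s in zip(keys, scrambled_keys)}
        )
        good = evaluate_dataset(ds, table, EvalProtocol(n_seeds=3), base_seed=2)
        bad = evaluate_dataset(ds, scrambled, EvalProtocol(n_seeds=3), base_seed=2)
        delta, sd = representation_delta(good, bad)
        assert delta > sd > 0
        d2, _ = representation_delta(bad, good)
        assert d2 == pytest.approx(-delta)

    def test_seed_misalignment_rejected(self):
        rng = np.random.default_rng(7)
        keys = [f"k{i}" for i in range(20)]
        table = random_rep(rng, keys)
        ds = make_eval_dataset(20, informative=False, task="classification", table=table, seed=7)
        a = evaluate_dataset(ds, table, EvalProtocol(n_seeds=2), base_seed=0)
        b = evaluate_dataset(ds, table, EvalProtocol(n_seeds=2), base_seed=9)
        with pytest.raises(ValueError):
            representation_delta(a, b)


class TestNeuralDistanceIndex:
    def _activity(self, rng, n_od=8, n_nr=6):
        odorants = [f"od{i}" for i in range(n_od)]
        neurons = [f"nr{i}" for i in range(n_nr)]
        return pd.DataFrame(rng.random((n_od, n_nr)), index=odorants, columns=neurons)

    def test_identity_gives_100(self):
        rng = np.random.default_rng(8)
        activity = self._activity(rng)
        # representation = the activity matrix itself
        table = RepresentationTable(
            "act", "correlation_centered",
            {od: activity.loc[od].to_numpy() for od in activity.index},
        )
        out = neural_distance_index(activity, [table], {"all": list(activity.columns)})
        assert out["act"] == pytest.approx(100.0)

    def test_independent_representation_near_zero(self):
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(10):
            activity = self._activity(rng)
            table = random_rep(rng, list(activity.index))
            out = neural_distance_index(activity, [table], {"all": list(activity.columns)})
            vals.append(out["feat"])
        assert abs(np.mean(vals)) < 20

    def test_neuron_order_invariance(self):
        rng = np.random.default_rng(10)
        activity = self._activity(rng)
        table = random_rep(rng, list(activity.index))
        cols = list(activity.columns)
        a = neural_distance_index(activity, [table], {"c": cols})
        b = neural_distance_index(activity, [table], {"c": cols[::-1]})
        assert a["feat"] == pytest.approx(b["feat"])


class TestEvalIO:
    def test_sidecar_round_trip(self, tmp_path):
        csv = tmp_path / "ds.csv"
        csv.write_text("key,t1\na,1\nb,0\nc,1\nd,0\n")
        sidecar = tmp_path / "ds.json"
        sidecar.write_text('{"name": "demo", "task": "classification"}')
        ds = read_eval_dataset(csv, sidecar)
        assert ds.name == "demo" and ds.task == "classification"
        assert ds.keys == ["a", "b", "c", "d"]
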