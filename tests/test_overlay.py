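"""Weighted overlay, classification, areas and accuracy metrics."""

import numpy as np
import pytest

from agrosuit.criteria import SCORE_NODATA
from agrosuit.grid import GridMismatchError
from agrosuit.overlay import (
    ConfusionMatrix,
    accuracy_metrics,
    classify_suitability,
    tabulate_areas,
    validate_points,
    weighted_overlay,
)
from conftest import make_layer


def score_stack(arrays, names=None):
    names = names or [f"l{i}" for i in range(len(arrays))]
    return {n: make_layer(a, nodata=SCORE_NODATA) for n, a in zip(names, arrays)}


class TestWeightedOverlay:
    def test_uniform_scores_give_that_score(self):
        for s in (1.0, 3.0):
            layers = score_stack([np.full((4, 4), s)] * 3)
            pacp = weighted_overlay(layers, {"l0": 0.5, "l1": 0.3, "l2": 0.2})
            assert np.allclose(pacp.values, s)

    def test_published_weight_groups_hand_value(self, hierarchy):
        """Climate-group layers at 3, all others at 2: 3(0.6) + 2(0.4) = 2.6."""
        from agrosuit.ahp import compose_weights

        weights = compose_weights(hierarchy)
        climate = {"rainfall", "avg_temp", "min_temp", "max_temp"}
        layers = {n: make_layer([[3.0 if n in climate else 2.0]]) for n in weights}
        pacp = weighted_overlay(layers, weights)
        w_climate = sum(w for n, w in weights.items() if n in climate)
        assert pacp.values[0, 0] == pytest.approx(2.0 + w_climate)
        assert pacp.values[0, 0] == pytest.approx(2.6, abs=0.01)

    def test_matches_per_cell_brute_force_exactly(self):
        rng = np.random.default_rng(13)
        arrays = [rng.integers(1, 4, size=(32, 32)).astype(float) for _ in range(5)]
        arrays[0][3, 4] = np.nan
        layers = score_stack(arrays)
        w = rng.dirichlet(np.ones(5))
        weights = {f"l{i}": float(w[i]) for i in range(5)}
        pacp = weighted_overlay(layers, weights).values
        for r in range(32):
            for c in range(32):
                if any(np.isnan(a[r, c]) for a in arrays):
                    assert np.isnan(pacp[r, c])
                else:
                    # independent per-cell loop in the same sorted-name order
                    acc = 0.0
                    for n in sorted(weights):
                        acc += weights[n] * layers[n].values[r, c]
                    assert pacp[r, c] == acc

    def test_monotone_in_any_single_layer(self):
        layers = score_stack([np.full((2, 2), 2.0)] * 3)
        weights = {"l0": 0.2, "l1": 0.3, "l2": 0.5}
        base = weighted_overlay(layers, weights).values[0, 0]
        for n in layers:
            bumped = {k: v for k, v in layers.items()}
            up = layers[n].values.copy()
            up[0, 0] = 3.0
            bumped[n] = layers[n].like(up, nodata=SCORE_NODATA)
            assert weighted_overlay(bumped, weights).values[0, 0] >= base

    def test_grid_mismatch_names_layer(self):
        a = make_layer(np.ones((4, 4)))
        b = make_layer(np.ones((5, 5)))
        with pytest.raises(GridMismatchError, match="bad"):
            weighted_overlay({"ok": a, "bad": b}, {"ok": 0.5, "bad": 0.5})

    def test_weight_sum_and_key_mismatch_rejected(self):
        a = make_layer(np.ones((2, 2)))
        with pytest.raises(ValueError, match="sum"):
            weighted_overlay({"a": a}, {"a": 0.9})
        with pytest.raises(ValueError, match="match"):
            weighted_overlay({"a": a}, {"b": 1.0})


class TestClassification:
    @pytest.mark.parametrize("pacp, expected", [(1.0, 1), (1.5, 1), (2.0, 2), (2.5, 3), (3.0, 3)])
    def test_default_equal_thirds_breaks(self, pacp, expected):
        out = classify_suitability(make_layer([[pacp]]))
        assert int(out.values[0, 0]) == expected

    def test_constant_pacp_single_class(self):
        out = classify_suitability(make_layer(np.full((6, 6), 2.9)))
        assert (out.values == 3).all()

    def test_invalid_breaks_rejected(self):
        with pytest.raises(ValueError, match="breaks"):
            classify_suitability(make_layer([[2.0]]), breaks=(2.5, 1.5))

    def test_nodata_preserved(self):
        out = classify_suitability(make_layer([[np.nan, 2.0]]))
        assert out.values[0, 0] == SCORE_NODATA


class TestAreas:
    def test_hand_tabulation(self):
        vals = np.concatenate([np.ones(100), np.full(200, 2), np.full(100, 3)])
        classes = make_layer(vals.reshape(20, 20), pixel_size=10.0, nodata=SCORE_NODATA)
        t = tabulate_areas(classes).set_index("class")
        assert t.loc["Unsuitable", "area_km2"] == pytest.approx(0.01)
        assert t.loc["Sub-suitable", "area_km2"] == pytest.approx(0.02)
        assert t.loc["Suitable", "percent"] == pytest.approx(25.0)
        assert t.loc["Total", "percent"] == 100.0
        assert t.drop("Total")["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_class_is_all_area(self):
        classes = make_layer(np.full((4, 4), 3.0), nodata=SCORE_NODATA)
        t = tabulate_areas(classes).set_index("class")
        assert t.loc["Suitable", "percent"] == 100.0

    def test_all_nodata_gives_empty_total(self):
        classes = make_layer(np.full((4, 4), float(SCORE_NODATA)), nodata=SCORE_NODATA)
        t = tabulate_areas(classes)
        assert t["area_km2"].sum() == 0.0

    def test_area_conservation_over_random_scenes(self):
        """Class areas always sum to the valid-cell area (100 seeds)."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = rng.choice([1.0, 2.0, 3.0, float(SCORE_NODATA)], size=(16, 16))
            classes = make_layer(vals, pixel_size=10.0, nodata=SCORE_NODATA)
            t = tabulate_areas(classes).set_index("class")
            valid = (vals != SCORE_NODATA).sum()
            assert t.drop("Total")["area_km2"].sum() == pytest.approx(valid * 100 / 1e6)
            if valid:
                assert t.drop("Total")["percent"].sum() == pytest.approx(100.0, abs=0.1)


class TestAccuracy:
    def test_diagonal_matrix_perfect(self):
        cm = ConfusionMatrix(labels=(1, 2, 3), counts=np.diag([10, 20, 30]))
        acc, kappa = accuracy_metrics(cm)
        assert acc == 1.0 and kappa == 1.0

    def test_hand_2x2_example(self):
        cm = ConfusionMatrix(labels=("a", "b"), counts=np.array([[40, 10], [10, 40]]))
        acc, kappa = accuracy_metrics(cm)
        assert acc == pytest.approx(0.8)
        assert kappa == pytest.approx(0.6)  # po 0.8, pe 0.5

    def test_uniform_matrix_chance_agreement(self):
        cm = ConfusionMatrix(labels=(1, 2, 3), counts=np.full((3, 3), 7))
        _, kappa = accuracy_metrics(cm)
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_marginal_reports_undefined_kappa(self):
        cm = ConfusionMatrix(labels=("a", "b"), counts=np.array([[50, 0], [0, 0]]))
        acc, kappa = accuracy_metrics(cm)
        assert acc == 1.0 and kappa is None

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(labels=("a",), counts=np.zeros((1, 1)))
        with pytest.raises(ValueError, match="empty"):
            accuracy_metrics(cm)


class TestValidatePoints:
    def test_points_report_predicted_class(self):
        classes = make_layer([[3.0, 1.0], [float(SCORE_NODATA), 2.0]],
                             pixel_size=10.0, nodata=SCORE_NODATA)
        table = validate_points(classes, [(5, 15, "farm"), (15, 15), (5, 5)])
        assert list(table["predicted"]) == ["Suitable", "Unsuitable", "unscored"]

    def test_points_in_suitable_cells_all_suitable(self, landscape, hierarchy):
        from agrosuit.pipeline import run_suitability

        res, _ = run_suitability(landscape.layers, hierarchy, legends=landscape.legends)
        vals = res.classes.values
        rows, cols = np.nonzero(vals == 3)
        px = res.classes.pixel_size
        x0, y0 = res.classes.origin
        pts = [(x0 + (c + 0.5) * px, y0 - (r + 0.5) * px) for r, c in zip(rows[:20], cols[:20])]
        table = validate_points(res.classes, pts)
        assert (table["predicted"] == "Suitable").all() and len(table) == 20
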