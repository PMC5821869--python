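"""Marker phenotyping and ductal discrimination."""

import numpy as np
import pandas as pd
import pytest

from hepaquant.phenotype import (
    DuctalDiscriminant,
    MarkerClassifier,
    PhenotypeRule,
    classify_double_if,
    classify_fov_ductality,
    classify_marker,
    train_ductal_model,
)


def _cells(dab):
    return pd.DataFrame({"id": np.arange(1, len(dab) + 1), "od_cyt_dab": dab})


class TestMarkerClassifier:
    def test_fixed_threshold_counts(self):
        cells = _cells([0.1] * 7 + [0.6] * 3)
        rule = PhenotypeRule("pck", "od_cyt_dab", "fixed", 0.3)
        out, summary = classify_marker(cells, rule)
        assert summary == {"n_pos": 3, "n_total": 10, "percent_pos": 30.0}
        assert (out["phenotype_pck"] == "positive").sum() == 3

    def test_all_below_threshold(self):
        cells = _cells([0.05, 0.1, 0.2])
        out, summary = classify_marker(
            cells, PhenotypeRule("pck", "od_cyt_dab", "fixed", 0.3)
        )
        assert summary["percent_pos"] == 0.0

    def test_empty_table_zero_percent(self):
        out, summary = classify_marker(
            _cells([]), PhenotypeRule("pck", "od_cyt_dab", "fixed", 0.3)
        )
        assert summary == {"n_pos": 0, "n_total": 0, "percent_pos": 0.0}

    def test_counts_partition_total(self, rng):
        dab = rng.uniform(0, 1, 200)
        out, summary = classify_marker(
            _cells(dab), PhenotypeRule("pck", "od_cyt_dab", "fixed", 0.5)
        )
        n_neg = (out["phenotype_pck"] == "negative").sum()
        assert summary["n_pos"] + n_neg == summary["n_total"] == 200
        assert 0.0 <= summary["percent_pos"] <= 100.0

    @pytest.mark.parametrize("mode", ["otsu", "gmm-2"])
    def test_data_driven_cut_separates_two_gaussians(self, mode, rng):
        x = np.concatenate(
            [rng.normal(0.1, 0.05, 350), rng.normal(0.6, 0.05, 150)]
        ).clip(0)
        labels = np.array([False] * 350 + [True] * 150)
        clf = MarkerClassifier(mode=mode).fit(x)
        assert (clf.predict(x) == labels).mean() >= 0.99

    def test_order_invariance_fixed_threshold(self, rng):
        dab = rng.uniform(0, 1, 50)
        rule = PhenotypeRule("m", "od_cyt_dab", "fixed", 0.4)
        _, s1 = classify_marker(_cells(dab), rule)
        _, s2 = classify_marker(_cells(dab[::-1]), rule)
        assert s1 == s2

    def test_affine_rescaling_invariance(self, rng):
        dab = rng.uniform(0, 1, 50)
        a, b = 2.5, 0.3
        s1 = MarkerClassifier("fixed", 0.4).fit(dab).predict(dab)
        s2 = MarkerClassifier("fixed", a * 0.4 + b).fit(a * dab + b).predict(a * dab + b)
        assert np.array_equal(s1, s2)

    def test_unimodal_distribution_yields_all_negative(self):
        x = np.full(100, 0.5)
        clf = MarkerClassifier(mode="otsu").fit(x)
        assert not clf.predict(x).any()

    def test_missing_feature_is_schema_error(self):
        with pytest.raises(KeyError):
            classify_marker(
                pd.DataFrame({"id": [1]}), PhenotypeRule("m", "od_cyt_dab", "fixed", 0.1)
            )

    def test_fixed_mode_requires_threshold(self):
        with pytest.raises(ValueError):
            PhenotypeRule("m", "od_cyt_dab", "fixed")


class TestDoubleIf:
    @pytest.mark.parametrize(
        "g,r,expected",
        [(0.8, 0.7, "double+"), (0.8, 0.2, "green+"), (0.2, 0.8, "red+"), (0.1, 0.1, "negative")],
    )
    def test_four_way_labels(self, g, r, expected):
        cells = pd.DataFrame({"id": [1], "int_cyt_green": [g], "int_cyt_red": [r]})
        out, counts = classify_double_if(
            cells,
            PhenotypeRule("green", "int_cyt_green", "fixed", 0.5),
            PhenotypeRule("red", "int_cyt_red", "fixed", 0.5),
        )
        assert out["if_label"].iloc[0] == expected

    def test_counts_partition_and_exclude_double_from_singles(self, rng):
        n = 300
        cells = pd.DataFrame(
            {
                "id": np.arange(n),
                "int_cyt_green": rng.uniform(0, 1, n),
                "int_cyt_red": rng.uniform(0, 1, n),
            }
        )
        _, counts = classify_double_if(
            cells,
            PhenotypeRule("green", "int_cyt_green", "fixed", 0.5),
            PhenotypeRule("red", "int_cyt_red", "fixed", 0.5),
        )
        total = (
            counts["green_only"] + counts["red_only"] + counts["double"] + counts["negative"]
        )
        assert total == counts["n_total"] == n


def _two_populations(rng, n_each=50, sep=True):
    """Feature draws for ductal vs non-ductal exemplars (means per the
    reported group differences; sd 10% of mean)."""
    ductal_mean = np.array([60.0, 0.8, 0.7])
    non_mean = np.array([25.0, 0.4, 0.3]) if sep else ductal_mean
    cols = ["area_um2", "od_nuc_haematoxylin", "od_cyt_dab"]
    d = pd.DataFrame(rng.normal(ductal_mean, 0.1 * ductal_mean, (n_each, 3)), columns=cols)
    n = pd.DataFrame(rng.normal(non_mean, 0.1 * np.abs(non_mean), (n_each, 3)), columns=cols)
    d["ductal_label"] = "ductal"
    n["ductal_label"] = "non_ductal"
    return pd.concat([d, n], ignore_index=True)


class TestDuctalDiscriminant:
    def test_separated_populations_high_heldout_accuracy(self):
        rng = np.random.default_rng(11)
        train = _two_populations(rng)
        test = _two_populations(rng)
        model = train_ductal_model(train)
        acc = (model.predict(test) == test["ductal_label"].to_numpy()).mean()
        assert acc >= 0.98

    def test_identical_populations_chance_accuracy(self):
        rng = np.random.default_rng(12)
        train = _two_populations(rng, n_each=200, sep=False)
        test = _two_populations(rng, n_each=200, sep=False)
        model = train_ductal_model(train)
        acc = (model.predict(test) == test["ductal_label"].to_numpy()).mean()
        assert abs(acc - 0.5) <= 0.1

    def test_ductal_scores_higher(self):
        rng = np.random.default_rng(13)
        train = _two_populations(rng)
        model = train_ductal_model(train)
        scores = model.decision_function(train)
        d = scores[(train["ductal_label"] == "ductal").to_numpy()]
        n = scores[(train["ductal_label"] == "non_ductal").to_numpy()]
        assert d.mean() > n.mean()

    def test_single_class_rejected(self):
        rng = np.random.default_rng(14)
        train = _two_populations(rng)
        only = train[train["ductal_label"] == "ductal"]
        with pytest.raises(ValueError):
            train_ductal_model(only)

    def test_too_few_exemplars_rejected(self):
        rng = np.random.default_rng(15)
        train = _two_populations(rng, n_each=4)
        with pytest.raises(ValueError):
            train_ductal_model(train)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(16)
        train = _two_populations(rng)
        model = train_ductal_model(train)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = DuctalDiscriminant.from_json(path)
        x = _two_populations(rng)
        assert np.array_equal(model.predict(x), loaded.predict(x))


class TestFovDuctality:
    @pytest.fixture
    def model(self):
        return train_ductal_model(_two_populations(np.random.default_rng(17)))

    def test_all_ductal_cells_give_portal_like(self, model):
        rng = np.random.default_rng(18)
        fov = _two_populations(rng, n_each=10)
        fov = fov[fov["ductal_label"] == "ductal"]
        assert classify_fov_ductality(fov, model)["label"] == "portal-like"

    def test_no_ductal_cells_give_central_like(self, model):
        rng = np.random.default_rng(19)
        fov = _two_populations(rng, n_each=10)
        fov = fov[fov["ductal_label"] == "non_ductal"]
        assert classify_fov_ductality(fov, model)["label"] == "central-like"

    def test_zero_positive_cells_undetermined(self, model):
        empty = _two_populations(np.random.default_rng(20)).iloc[:0]
        out = classify_fov_ductality(empty, model)
        assert out["label"] == "undetermined"
        assert out["n_positive"] == 0

    def test_reports_mean_features(self, model):
        fov = _two_populations(np.random.default_rng(21), n_each=10)
        out = classify_fov_ductality(fov, model)
        assert set(out["mean_features"]) == {
            "area_um2", "od_nuc_haematoxylin", "od_cyt_dab",
        }
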