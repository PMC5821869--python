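"""Surrogate measures, ordinal binning and composite scoring."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from hepaquant.geometry import FovGeometry
from hepaquant.scoring import (
    CATEGORIES,
    CATEGORY_MAX,
    BinningScheme,
    SurrogateScores,
    bin_scores,
    default_binning_scheme,
    score_sample,
    surrogate_measures,
)


@pytest.fixture
def scheme():
    return BinningScheme(
        {
            "piecemeal": (10, 20, 30, 40),
            "confluent": (0.01, 0.02, 0.03, 0.04, 0.05, 0.06),
            "lobular": (1, 2, 3, 4),
            "portal": (10, 20, 30, 40),
        }
    )


class TestBinningScheme:
    def test_default_scheme_loads_and_validates(self):
        scheme = default_binning_scheme()
        for cat in CATEGORIES:
            assert len(scheme.thresholds[cat]) == CATEGORY_MAX[cat]

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            BinningScheme(
                {
                    "piecemeal": (10, 10, 30, 40),
                    "confluent": (1, 2, 3, 4, 5, 6),
                    "lobular": (1, 2, 3, 4),
                    "portal": (1, 2, 3, 4),
                }
            )

    def test_missing_category_rejected(self):
        with pytest.raises(ValueError):
            BinningScheme({"piecemeal": (1, 2, 3, 4)})

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            BinningScheme(
                {
                    "piecemeal": (1, 2, 3),
                    "confluent": (1, 2, 3, 4, 5, 6),
                    "lobular": (1, 2, 3, 4),
                    "portal": (1, 2, 3, 4),
                }
            )


class TestBinScores:
    def test_composite_is_sum_of_ordinals(self, scheme):
        measures = {"piecemeal": 35.0, "confluent": 0.025, "lobular": 1.5, "portal": 45.0}
        scored = bin_scores(measures, scheme)
        assert scored.ordinal == {"piecemeal": 3, "confluent": 2, "lobular": 1, "portal": 4}
        assert scored.composite == 10

    def test_zero_measures_zero_composite(self, scheme):
        scored = bin_scores(dict.fromkeys(CATEGORIES, 0.0), scheme)
        assert scored.composite == 0

    def test_boundary_values_fall_in_lower_bin(self, scheme):
        # brute-force scan over every threshold boundary of every category
        for cat in CATEGORIES:
            for k, t in enumerate(scheme.thresholds[cat]):
                at = bin_scores(dict.fromkeys(CATEGORIES, 0.0) | {cat: float(t)}, scheme)
                above = bin_scores(
                    dict.fromkeys(CATEGORIES, 0.0) | {cat: float(t) + 1e-9}, scheme
                )
                assert at.ordinal[cat] == k
                assert above.ordinal[cat] == k + 1

    def test_ordinal_monotone_in_measure(self, scheme, rng):
        for cat in CATEGORIES:
            ms = np.sort(rng.uniform(0, 60, 50))
            ords = [
                bin_scores(dict.fromkeys(CATEGORIES, 0.0) | {cat: float(m)}, scheme).ordinal[cat]
                for m in ms
            ]
            assert all(a <= b for a, b in zip(ords, ords[1:]))

    def test_composite_range(self, scheme, rng):
        for _ in range(20):
            measures = {c: float(rng.uniform(0, 100)) for c in CATEGORIES}
            s = bin_scores(measures, scheme)
            assert 0 <= s.composite <= 18
            assert s.composite == sum(s.ordinal.values())


class TestScoreSample:
    def test_single_fov_identity(self, scheme):
        fov = SurrogateScores(12.0, 0.015, 2.5, 33.0)
        agg = score_sample([fov], scheme)
        assert agg.measures == fov.measures
        assert agg == bin_scores(fov, scheme)

    def test_equal_area_mean(self, scheme):
        a = SurrogateScores(10.0, 0.01, 1.0, 10.0)
        b = SurrogateScores(30.0, 0.03, 3.0, 30.0)
        agg = score_sample([a, b], scheme, [1.0, 1.0])
        assert agg.measures == {"piecemeal": 20.0, "confluent": 0.02, "lobular": 2.0, "portal": 20.0}

    def test_area_weighting(self, scheme):
        a = SurrogateScores(10.0, 0.0, 0.0, 0.0)
        b = SurrogateScores(40.0, 0.0, 0.0, 0.0)
        agg = score_sample([a, b], scheme, [3.0, 1.0])
        assert agg.piecemeal_measure == pytest.approx(17.5)

    def test_empty_fov_list_rejected(self, scheme):
        with pytest.raises(ValueError):
            score_sample([], scheme)


def _mask_with_disk(shape, centre, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = disk(centre, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestSurrogateMeasures:
    @pytest.fixture
    def geometry(self):
        return FovGeometry(400, 400, 0.5)

    def _cells(self, xy, positive=True):
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return pd.DataFrame(
            {
                "id": np.arange(1, len(xy) + 1),
                "x": xy[:, 0],
                "y": xy[:, 1],
                "phenotype_cd45": "positive" if positive else "negative",
            }
        )

    def test_no_cd45_no_necrosis_all_zero(self, geometry):
        masks = {
            "tissue": np.ones(geometry.shape, dtype=bool),
            "necrosis": np.zeros(geometry.shape, dtype=bool),
            "portal": _mask_with_disk(geometry.shape, (200, 200), 50),
        }
        s = surrogate_measures(self._cells(np.empty((0, 2))), masks, geometry)
        assert s.measures == dict.fromkeys(CATEGORIES, 0.0)

    def test_portal_density_is_count_over_area(self, geometry):
        # portal disk of exactly known pixel area; 10 CD45+ cells inside
        portal = _mask_with_disk(geometry.shape, (200, 200), 100)
        area_mm2 = geometry.px_area_to_mm2(int(portal.sum()))
        cells = self._cells([(200, 200)] * 0 + [(195 + i, 200) for i in range(10)])
        masks = {
            "tissue": np.ones(geometry.shape, dtype=bool),
            "necrosis": np.zeros(geometry.shape, dtype=bool),
            "portal": portal,
        }
        s = surrogate_measures(cells, masks, geometry)
        assert s.portal_measure == pytest.approx(10.0 / area_mm2)

    def test_confluent_is_necrotic_fraction(self, geometry):
        necrosis = _mask_with_disk(geometry.shape, (100, 100), 60)
        masks = {
            "tissue": np.ones(geometry.shape, dtype=bool),
            "necrosis": necrosis,
            "portal": np.zeros(geometry.shape, dtype=bool),
        }
        s = surrogate_measures(self._cells(np.empty((0, 2))), masks, geometry)
        assert s.confluent_measure == pytest.approx(necrosis.mean())

    def test_negative_cells_do_not_count(self, geometry):
        portal = _mask_with_disk(geometry.shape, (200, 200), 100)
        cells = self._cells([(200, 200)] * 5, positive=False)
        masks = {
            "tissue": np.ones(geometry.shape, dtype=bool),
            "necrosis": np.zeros(geometry.shape, dtype=bool),
            "portal": portal,
        }
        s = surrogate_measures(cells, masks, geometry)
        assert s.portal_measure == 0.0

    def test_missing_phenotype_is_schema_error(self, geometry):
        cells = pd.DataFrame({"id": [1], "x": [1.0], "y": [1.0]})
        masks = {
            "tissue": np.ones(geometry.shape, dtype=bool),
            "necrosis": np.zeros(geometry.shape, dtype=bool),
            "portal": np.zeros(geometry.shape, dtype=bool),
        }
        with pytest.raises(KeyError):
            surrogate_measures(cells, masks, geometry)

    def test_missing_mask_rejected(self, geometry):
        with pytest.raises(KeyError):
            surrogate_measures(
                self._cells(np.empty((0, 2))),
                {"tissue": np.ones(geometry.shape, dtype=bool)},
                geometry,
            )
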