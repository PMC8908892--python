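import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raylife.diet import (
    PREY_GROUPS,
    StomachSample,
    bray_curtis,
    classify_life_stage,
    composition_matrix,
    ioi,
    pairwise_permanova,
    permanova,
    pct_freq,
    pct_weight,
)


class TestLifeStage:
    @pytest.mark.parametrize(
        "age, dw, mature, expected",
        [
            (0, 14.0, 0, "YOY"),
            (0.0, 25.0, 1, "YOY"),  # age takes precedence
            (3, 25.0, 1, "adult"),
            (2, 19.0, 0, "juvenile"),
            (5, 25.0, 0, "juvenile"),  # large but immature
            (2, 21.0, 1, "adult"),  # at the boundary, ties go to adult
            (None, 25.0, 1, "adult"),  # unaged specimens cannot be YOY
        ],
    )
    def test_classification(self, age, dw, mature, expected):
        assert classify_life_stage(age, dw, mature, dw50=21.0) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            classify_life_stage(-1, 20.0, 0, 21.0)


class TestPercentages:
    @pytest.mark.parametrize(
        "mass, body, expected", [(0.0, 300.0, 0.0), (5.0, 500.0, 1.0)]
    )
    def test_pct_weight(self, mass, body, expected):
        assert pct_weight(mass, body) == pytest.approx(expected)

    def test_pct_weight_scales_linearly_with_prey_mass(self):
        assert pct_weight(6.0, 400.0) == pytest.approx(3 * pct_weight(2.0, 400.0))

    @pytest.mark.parametrize(
        "hits, total, expected",
        [(24, 24, 100.0), (23, 24, 95.8), (0, 10, 0.0)],
    )
    def test_pct_freq(self, hits, total, expected):
        assert round(pct_freq(hits, total), 1) == pytest.approx(expected)

    def test_pct_freq_invalid(self):
        with pytest.raises(ValueError):
            pct_freq(1, 0)
        with pytest.raises(ValueError):
            pct_freq(5, 4)


class TestIOI:
    # frozen from an independent spreadsheet-style computation on the fixture
    EXPECTED = {
        "crustaceans": (0.466667, 66.666667, 28.636428),
        "polychaetes": (0.133333, 33.333333, 14.275558),
        "bivalves": (0.166667, 33.333333, 14.289777),
        "other_molluscs": (0.0, 0.0, 0.0),
        "teleosts": (0.266667, 33.333333, 14.332433),
        "unidentified": (0.066667, 66.666667, 28.465804),
    }

    def test_hand_computed_fixture(self, four_stomachs):
        table = ioi(four_stomachs, stratify_by_life_stage=False)
        for g, (w, f, val) in self.EXPECTED.items():
            assert table.loc[g, "pct_weight"] == pytest.approx(w, abs=1e-4)
            assert table.loc[g, "pct_freq"] == pytest.approx(f, abs=1e-4)
            assert table.loc[g, "ioi"] == pytest.approx(val, abs=0.1)
        assert table["ioi"].sum() == pytest.approx(100.0)

    def test_single_prey_group_gets_everything(self):
        s = StomachSample("a", "adult", 300.0, masses={"polychaetes": 2.0})
        table = ioi([s], stratify_by_life_stage=False)
        assert table.loc["polychaetes", "ioi"] == pytest.approx(100.0)
        assert table["ioi"].sum() == pytest.approx(100.0)

    def test_stratified_sums_to_100_per_stage(self, four_stomachs):
        extra = [
            StomachSample("y1", "YOY", 80.0, masses={"crustaceans": 0.2}),
            StomachSample("y2", "YOY", 90.0, masses={"unidentified": 0.1}),
            StomachSample("j1", "juvenile", 200.0, masses={"polychaetes": 1.0}),
            StomachSample("j2", "juvenile", 210.0, masses={"bivalves": 0.4}),
        ]
        table = ioi(four_stomachs + extra)
        sums = table.groupby("life_stage")["ioi"].sum()
        assert np.allclose(sums.values, 100.0)

    def test_empty_stratum_skipped_with_warning(self):
        stomachs = [
            StomachSample("a", "adult", 300.0, masses={"bivalves": 1.0}),
            StomachSample("a2", "adult", 280.0, masses={"bivalves": 0.5}),
            StomachSample("y", "YOY", 90.0, masses={}),
        ]
        with pytest.warns(RuntimeWarning):
            table = ioi(stomachs)
        assert set(table.index.get_level_values("life_stage")) == {"adult"}

    def test_pooled_weight_method(self, four_stomachs):
        table = ioi(four_stomachs, stratify_by_life_stage=False, weight_method="pooled")
        # pooled: 100 * (5+1) / (500+250+1000) for crustaceans
        assert table.loc["crustaceans", "pct_weight"] == pytest.approx(600 / 1750)
        assert table["ioi"].sum() == pytest.approx(100.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ioi_normalization_invariant(self, seed):
        rng = np.random.default_rng(seed)
        stomachs = []
        for i in range(rng.integers(2, 12)):
            masses = {
                g: float(rng.random() < 0.5) * float(rng.gamma(1.5, 0.4))
                for g in PREY_GROUPS
            }
            stomachs.append(
                StomachSample(
                    f"s{i}",
                    "adult",
                    float(rng.uniform(60, 1200)),
                    masses=masses,
                )
            )
        if not any(s.has_food for s in stomachs):
            return
        table = ioi(stomachs, stratify_by_life_stage=False)
        assert table["ioi"].sum() == pytest.approx(100.0)
        assert ((table["pct_freq"] >= 0) & (table["pct_freq"] <= 100)).all()

    def test_freq_invariant_to_mass_rescaling(self, four_stomachs):
        doubled = [
            StomachSample(
                s.specimen_id,
                s.life_stage,
                s.body_mass,
                masses={g: 2 * m for g, m in s.masses.items()},
                counts=s.counts,
            )
            for s in four_stomachs
        ]
        t1 = ioi(four_stomachs, stratify_by_life_stage=False)
        t2 = ioi(doubled, stratify_by_life_stage=False)
        assert np.allclose(t1["pct_freq"], t2["pct_freq"])
        assert np.allclose(2 * t1["pct_weight"], t2["pct_weight"])


class TestComposition:
    def test_rows_sum_to_one_and_empty_excluded(self, four_stomachs):
        m = composition_matrix(four_stomachs)
        assert list(m.index) == ["s1", "s2", "s3"]  # s4 is empty
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_count_response(self, four_stomachs):
        m = composition_matrix(four_stomachs, response="count")
        assert m.loc["s1", "crustaceans"] == pytest.approx(3 / 5)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        x = np.array([[0.2, 0.8], [0.2, 0.8]])
        assert bray_curtis(x)[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert bray_curtis(x)[0, 1] == pytest.approx(1.0)

    def test_three_row_hand_computation(self):
        x = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.25, 0.5, 0.25]])
        d = bray_curtis(x)
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 2] == pytest.approx(0.25)
        assert d[1, 2] == pytest.approx(0.25)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestPermanova:
    def _clusters(self, rng, sep=0.0, n_per=8):
        base = rng.dirichlet(np.ones(6), size=3 * n_per)
        labels = np.repeat(["a", "b", "c"], n_per)
        if sep:
            for i, g in enumerate("abc"):
                base[labels == g, i] += sep
            base /= base.sum(axis=1, keepdims=True)
        return base, labels

    def test_matches_scikit_bio_pseudo_f(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(0)
        x, labels = self._clusters(rng, sep=0.4)
        d = bray_curtis(x)
        mine = permanova(d, labels, n_perm=99, seed=1)
        theirs = skbio_permanova(DistanceMatrix(d), labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_separated_clusters_hit_p_floor(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 0.01, size=(18, 6))
        x[:6, 0] += 1.0
        x[6:12, 2] += 1.0
        x[12:, 4] += 1.0
        x /= x.sum(axis=1, keepdims=True)
        labels = np.repeat(["a", "b", "c"], 6)
        res = permanova(bray_curtis(x), labels, n_perm=999, seed=2)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r_squared > 0.9

    def test_r_squared_in_unit_interval_and_reproducible(self):
        rng = np.random.default_rng(3)
        x, labels = self._clusters(rng)
        d = bray_curtis(x)
        r1 = permanova(d, labels, n_perm=199, seed=5)
        r2 = permanova(d, labels, n_perm=199, seed=5)
        assert 0.0 <= r1.r_squared <= 1.0
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 200
        assert r1.ss_total == pytest.approx(r1.ss_between + r1.ss_within)

    def test_singleton_group_rejected(self):
        d = bray_curtis(np.random.default_rng(0).random((5, 3)))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a", "a", "b"], n_perm=99, seed=0)

    def test_pairwise_three_groups(self):
        rng = np.random.default_rng(4)
        x, labels = self._clusters(rng, sep=0.5)
        pw = pairwise_permanova(bray_curtis(x), labels, n_perm=199, seed=6)
        assert len(pw) == 3
        assert list(zip(pw["group_1"], pw["group_2"])) == [
            ("a", "b"), ("a", "c"), ("b", "c")
        ]
        assert (pw["p_holm"] >= pw["p_value"]).all()
        # strongly divergent profiles: every pair significant
        assert (pw["p_holm"] < 0.05).all()
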