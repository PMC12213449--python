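"""AUC, metadata baseline, modality combinations, comorbidity statistics."""


import numpy as np
import pytest
from scipy import stats

from dementnet.evaluation import (auc, additive_value, auc_by_site,
                                  chi_squared_dependence, comorbidity_scan,
                                  evaluate_subset, first_visit_subset,
                                  metadata_baseline,
                                  modality_combination_analysis)
from dementnet.synthetic import generate_cohort, null_effects
from conftest import make_patient


def pair_count_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_matches_pair_counting_oracle_small_n(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 1)  # provoke ties
            assert auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12)

    def test_single_class_undefined_not_half(self):
        with pytest.raises(ValueError):
            auc([0.5, 0.6], [1, 1])
        res = evaluate_subset([0.5, 0.6], [1, 1], "dementia", "all")
        assert res.auc is None and "absent" in res.note

    def test_per_site_machinery(self):
        scores = [0.9, 0.1, 0.8, 0.2, 0.7]
        labels = [1, 0, 1, 0, 1]
        sites = ["a", "a", "b", "b", "b"]
        results = auc_by_site(scores, labels, sites, "dementia")
        assert {r.subset for r in results} == {"site:a", "site:b"}
        assert all(r.auc == 1.0 for r in results)


class TestMetadataBaseline:
    def test_uninformative_metadata_near_chance(self):
        patients, _ = generate_cohort(600, effects=null_effects(), seed=3,
                                      render_volumes=False)
        result = metadata_baseline(patients[:300], patients[300:], "dementia",
                                   seed=0)
        assert result["auc"] == pytest.approx(0.5, abs=0.08)

    def test_predictive_modality_found(self):
        patients, _ = generate_cohort(300, seed=4, render_volumes=False)
        # default effects: age gap + modality contingency make metadata useful
        result = metadata_baseline(patients[:150], patients[150:], "dementia",
                                   seed=0)
        assert result["auc"] > 0.7

    def test_features_exclude_image_content(self):
        patients, _ = generate_cohort(50, seed=5, render_volumes=False)
        result = metadata_baseline(patients[:25], patients[25:], "dementia")
        from dementnet.evaluation import METADATA_FEATURES

        assert set(result["features"]) <= set(METADATA_FEATURES)


def test_additive_value_is_difference():
    assert additive_value(0.9, 0.6) == pytest.approx(0.3)
    assert additive_value(0.7, 0.7) == 0.0


class TestModalityCombinations:
    def test_buckets_partition_patients(self):
        patients, _ = generate_cohort(80, seed=6, render_volumes=False)
        labels = np.array([p.labels["dementia"] for p in patients])
        scores = np.linspace(0, 1, len(patients))
        table = modality_combination_analysis(scores, labels, patients,
                                              "dementia")
        buckets = table[table["kind"] == "image_count"]
        assert buckets[["n_cases", "n_controls"]].to_numpy().sum() == len(
            patients)

    def test_singleton_diagonal_covers_modalities(self):
        patients, _ = generate_cohort(60, seed=7, render_volumes=False)
        labels = np.array([p.labels["dementia"] for p in patients])
        table = modality_combination_analysis(
            np.linspace(0, 1, len(patients)), labels, patients, "dementia")
        mods = set()
        for p in patients:
            mods |= {im.modality for im in p.images}
        singles = set(table[table["kind"] == "modality_pair"]["cell"])
        assert mods <= singles


class TestComorbidityStatistics:
    def test_chi_squared_hand_value(self):
        a = np.repeat([0, 0, 1, 1], [10, 20, 30, 40])
        b = np.tile(0, 100)
        b = np.concatenate([np.zeros(10), np.ones(20), np.zeros(30),
                            np.ones(40)]).astype(int)
        chi2, _ = chi_squared_dependence(a, b)
        assert chi2 == pytest.approx(0.7937, abs=1e-4)

    def test_chi_squared_matches_formula_recomputation(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a = rng.integers(0, 2, 60)
            b = rng.integers(0, 2, 60)
            chi2, _ = chi_squared_dependence(a, b)
            table = np.array([[np.sum((a == i) & (b == j)) for j in (0, 1)]
                              for i in (0, 1)])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            manual = ((table - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(manual, abs=1e-9)

    def test_kruskal_matches_scipy_on_groups(self):
        rng = np.random.default_rng(9)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        codes = [{"I10"} if rng.random() < 0.5 else set() for _ in range(80)]
        df = comorbidity_scan(scores, labels, codes, "dementia", min_count=10)
        row = df[df["code"] == "I10"].iloc[0]
        has = np.array(["I10" in c for c in codes])
        perf = 1 - np.abs(labels - scores)
        h, p = stats.kruskal(perf[has], perf[~has])
        assert row["kw_H"] == pytest.approx(h, abs=1e-9)
        assert row["kw_p"] == pytest.approx(p, abs=1e-9)

    def test_identical_distributions_null(self):
        scores = np.tile([0.2, 0.4, 0.6, 0.8], 10)
        labels = np.ones(40)
        # first and second halves carry identical score distributions
        codes = [{"I10"} if i < 20 else set() for i in range(40)]
        df = comorbidity_scan(scores, labels, codes, "dementia", min_count=5)
        row = df[df["code"] == "I10"].iloc[0]
        assert row["kw_H"] == pytest.approx(0.0, abs=1e-9)
        assert row["kw_p"] > 0.99

    def test_sign_recovery_of_planted_bad_code(self):
        rng = np.random.default_rng(10)
        recovered = 0
        for _ in range(100):
            n = 200
            labels = rng.integers(0, 2, n)
            has_code = rng.random(n) < 0.3
            noise = rng.normal(0, 0.05, n)
            # patients with the code get systematically worse predictions
            err = np.where(has_code, 0.45, 0.1) + noise
            scores = np.clip(np.abs(labels - err), 0, 1)
            codes = [{"X01"} if h else set() for h in has_code]
            df = comorbidity_scan(scores, labels, codes, "dementia",
                                  min_count=10)
            if df[df["code"] == "X01"].iloc[0]["effect"] < 0:
                recovered += 1
        assert recovered >= 95

    def test_rare_codes_skipped_and_listed(self):
        scores = np.linspace(0, 1, 50)
        labels = np.ones(50)
        codes = [{"RARE"} if i < 3 else set() for i in range(50)]
        df = comorbidity_scan(scores, labels, codes, "dementia", min_count=20)
        assert "RARE" in df.attrs["skipped_codes"]

    def test_bh_adjustment_present(self):
        rng = np.random.default_rng(11)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        codes = [set(np.array(["A01", "B02", "C03"])[rng.random(3) < 0.4])
                 for _ in range(100)]
        df = comorbidity_scan(scores, labels, codes, "dementia", min_count=10)
        assert (df["kw_p_adj"] >= df["kw_p"] - 1e-12).all()


class TestFirstVisit:
    def test_earliest_only_and_idempotent(self):
        p = make_patient("p0", n_images=3, ages=[70.0, 60.0, 60.0])
        sub = first_visit_subset([p])[0]
        assert [im.age_at_scan for im in sub.images] == [60.0, 60.0]
        again = first_visit_subset([sub])[0]
        assert [im.image_id for im in again.images] == [
            im.image_id for im in sub.images]

    def test_single_image_unchanged(self):
        p = make_patient("p0", n_images=1)
        sub = first_visit_subset([p])[0]
        assert [im.image_id for im in sub.images] == [
            im.image_id for im in p.images]
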