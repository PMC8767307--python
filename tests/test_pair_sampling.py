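from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from auscon.pair_sampling import (ALL_SCHEMES, ContrastiveBatch, SchemeConfig,
                                  build_negative_constrained_batches,
                                  build_unconstrained_batches, eligible_pairs,
                                  positive_views_same_patient, validate_batch,
                                  weak_label_positives)

from .conftest import toy_dataset, toy_metadata


def _cohort(rows):
    return toy_dataset(toy_metadata(rows))


def two_rec_cohort(n_patients, age=None, sex=None, locs=("trachea", "trachea"),
                   start=0):
    rows = []
    for p in range(start, start + n_patients):
        a = age or ("adult" if p % 2 == 0 else "child")
        s = sex or ("female" if p % 3 == 0 else "male")
        for r, loc in enumerate(locs):
            rows.append((f"p{p}_r{r}", f"p{p}", a, s, loc, "normal"))
    return rows


class TestSchemeConfig:
    def test_twelve_schemes_resolve(self):
        assert len(ALL_SCHEMES) == 12
        for name in ALL_SCHEMES:
            cfg = SchemeConfig.from_name(name)
            assert cfg.name == name

    def test_unknown_scheme_lists_valid_names(self):
        with pytest.raises(ValueError, match="12 valid schemes"):
            SchemeConfig.from_name("neg_sim_height")

    def test_weak_label_only_for_pos_sim_age(self):
        assert SchemeConfig.from_name("pos_sim_age").weak_label_field == "age_band"
        with pytest.raises(ValueError):
            SchemeConfig(name="neg_sim_age", mode="metadata",
                         weak_label_field="age_band")


class TestEligiblePairs:
    def test_same_location_pair_eligible(self):
        ds = _cohort([("a", "p1", "adult", "male", "anterior left", "normal"),
                      ("b", "p1", "adult", "male", "anterior left", "normal")])
        pairs = eligible_pairs(ds, SchemeConfig.from_name("pos_same_loc"))
        assert pairs["p1"] == [(0, 1)]

    def test_different_location_pair_ineligible_under_same_loc(self):
        ds = _cohort([("a", "p1", "adult", "male", "trachea", "normal"),
                      ("b", "p1", "adult", "male", "posterior right", "normal")])
        pairs = eligible_pairs(ds, SchemeConfig.from_name("pos_same_loc"))
        assert pairs["p1"] == []
        pairs_dif = eligible_pairs(ds, SchemeConfig.from_name("pos_dif_loc"))
        assert pairs_dif["p1"] == [(0, 1)]

    def test_counts_match_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        locs = ["trachea", "anterior left", "posterior right"]
        rows = []
        for p in range(10):
            for r in range(int(rng.integers(2, 5))):
                rows.append((f"p{p}_r{r}", f"p{p}", "adult", "male",
                             locs[int(rng.integers(3))], "normal"))
        ds = _cohort(rows)
        meta = ds.metadata
        for name in ("pos_same_loc", "pos_dif_loc", "neg_sim_age"):
            scheme = SchemeConfig.from_name(name)
            got = {p: len(v) for p, v in eligible_pairs(ds, scheme).items()}
            want = {}
            for p, rows_p in meta.groupby("patient_id"):
                cnt = 0
                for i, j in combinations(rows_p.index, 2):
                    li, lj = meta.at[i, "location"], meta.at[j, "location"]
                    if scheme.positive_rule == "same_location":
                        cnt += li == lj
                    elif scheme.positive_rule == "different_location":
                        cnt += li != lj
                    else:
                        cnt += 1
                want[str(p)] = cnt
            assert got == want


class TestPositiveViews:
    def test_pairs_are_same_patient_distinct_recordings(self):
        ds = _cohort(two_rec_cohort(6))
        rng = np.random.default_rng(0)
        for i, j in positive_views_same_patient(
                ds, SchemeConfig.from_name("neg_sim_age"), rng):
            assert i != j
            assert (ds.metadata.at[i, "patient_id"]
                    == ds.metadata.at[j, "patient_id"])

    def test_ineligible_patient_skipped_with_warning(self, caplog):
        rows = two_rec_cohort(3) + [("lone_r0", "lone", "adult", "male",
                                     "trachea", "normal")]
        ds = _cohort(rows)
        with caplog.at_level("WARNING"):
            out = list(positive_views_same_patient(
                ds, SchemeConfig.from_name("neg_sim_age"),
                np.random.default_rng(0)))
        assert len(out) == 3
        assert any("lone" in rec.message for rec in caplog.records)

    def test_no_eligible_patient_errors(self):
        ds = _cohort([("a", "p1", "adult", "male", "trachea", "normal")])
        with pytest.raises(ValueError, match="no patient"):
            list(positive_views_same_patient(
                ds, SchemeConfig.from_name("neg_sim_age"),
                np.random.default_rng(0)))


class TestNegativeConstrainedBatches:
    def test_homogeneous_cohort_always_valid(self):
        ds = _cohort(two_rec_cohort(10, age="adult"))
        scheme = SchemeConfig.from_name("neg_sim_age")
        for batch in build_negative_constrained_batches(
                ds, scheme, 4, np.random.default_rng(0), n_batches=20):
            assert validate_batch(batch, scheme) == []
            assert batch.trait_value == ("adult",)

    def test_age_sex_batches_lie_in_one_cell(self):
        rows = []
        rows += two_rec_cohort(8, age="adult", sex="female", start=0)
        rows += two_rec_cohort(8, age="adult", sex="male", start=100)
        rows += two_rec_cohort(8, age="child", sex="female", start=200)
        rows += two_rec_cohort(8, age="child", sex="male", start=300)
        ds = _cohort(rows)
        scheme = SchemeConfig.from_name("neg_sim_age_sex")
        for batch in build_negative_constrained_batches(
                ds, scheme, 6, np.random.default_rng(1), n_batches=100):
            cells = set(zip(batch.metadata["age_band"], batch.metadata["sex"]))
            assert len(cells) == 1
            assert validate_batch(batch, scheme) == []

    def test_batch_origin_frequencies_match_sampling_law(self):
        # cells {adult-F: 20, adult-M: 3, child-F: 17, child-M: 0}, batch 16:
        # only adult-F and child-F are feasible, drawn with probability
        # proportional to their eligible-patient counts (20/37, 17/37)
        rows = []
        rows += two_rec_cohort(20, age="adult", sex="female", start=0)
        rows += two_rec_cohort(3, age="adult", sex="male", start=100)
        rows += two_rec_cohort(17, age="child", sex="female", start=200)
        ds = _cohort(rows)
        scheme = SchemeConfig.from_name("neg_sim_age_sex")
        n = 2000
        counts = {}
        for batch in build_negative_constrained_batches(
                ds, scheme, 16, np.random.default_rng(2), n_batches=n):
            counts[batch.trait_value] = counts.get(batch.trait_value, 0) + 1
        assert set(counts) == {("adult", "female"), ("child", "female")}
        p = 20 / 37
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(counts[("adult", "female")] - n * p) < 4 * sigma

    def test_infeasible_batch_size_reports_counts(self):
        ds = _cohort(two_rec_cohort(3, age="adult"))
        with pytest.raises(ValueError, match="per-value counts"):
            next(iter(build_negative_constrained_batches(
                ds, SchemeConfig.from_name("neg_sim_age"), 16,
                np.random.default_rng(0), n_batches=1)))

    def test_fixed_seed_reproduces_batch_sequence(self):
        ds = _cohort(two_rec_cohort(12))
        scheme = SchemeConfig.from_name("neg_sim_age")

        def run():
            return [b.recording_indices for b in build_negative_constrained_batches(
                ds, scheme, 4, np.random.default_rng(7), n_batches=10)]

        assert run() == run()

    def test_distinct_patients_within_batch(self):
        ds = _cohort(two_rec_cohort(10, age="adult"))
        for batch in build_negative_constrained_batches(
                ds, SchemeConfig.from_name("neg_sim_age"), 8,
                np.random.default_rng(3), n_batches=20):
            b = batch.batch_size
            patients = batch.metadata["patient_id"][:b]
            assert patients.nunique() == b


class TestWeakLabelPositives:
    def _batch(self, ages):
        n = len(ages)
        rows = [(f"r{i}", f"p{i % (n // 2)}", ages[i], "male", "trachea",
                 "normal") for i in range(n)]
        meta = toy_metadata(rows)
        ds = toy_dataset(meta)
        return ContrastiveBatch(views=ds.spectrograms,
                                recording_indices=list(range(n)),
                                metadata=meta)

    def test_all_same_band_makes_p_equal_a(self):
        batch = self._batch(["adult"] * 8)
        P = weak_label_positives(batch, "age_band")
        for i in range(8):
            assert P[i] == batch.candidate_sets[i]

    def test_alternating_bands_counted_by_brute_force(self):
        # 16 patients' views: first 8 adult pairs then 8 child pairs per view
        ages = ["adult"] * 8 + ["child"] * 8 + ["adult"] * 8 + ["child"] * 8
        n = 32
        rows = [(f"r{i}", f"p{i % 16}", ages[i], "male", "trachea", "normal")
                for i in range(n)]
        meta = toy_metadata(rows)
        batch = ContrastiveBatch(views=[None] * n,
                                 recording_indices=list(range(n)),
                                 metadata=meta)
        P = weak_label_positives(batch, "age_band")
        for i in range(n):
            brute = {j for j in range(n)
                     if j != i and ages[j] == ages[i]} | {batch.partner(i)}
            assert set(P[i]) == brute
            assert len(P[i]) == 15  # same-band views (partner shares the band)

    def test_missing_field_errors(self):
        batch = self._batch(["adult"] * 4)
        batch.metadata.loc[1, "age_band"] = pd.NA
        with pytest.raises(ValueError, match="age_band"):
            weak_label_positives(batch, "age_band")


class TestValidateBatch:
    def test_valid_batch_has_no_violations(self):
        ds = _cohort(two_rec_cohort(6, age="adult"))
        scheme = SchemeConfig.from_name("neg_sim_age")
        batch = next(iter(build_negative_constrained_batches(
            ds, scheme, 4, np.random.default_rng(0), n_batches=1)))
        assert validate_batch(batch, scheme) == []

    def test_single_trait_mismatch_named_by_index(self):
        ds = _cohort(two_rec_cohort(6, sex="female"))
        scheme = SchemeConfig.from_name("neg_sim_sex")
        batch = next(iter(build_negative_constrained_batches(
            ds, scheme, 4, np.random.default_rng(0), n_batches=1)))
        batch.metadata.loc[2, "sex"] = "male"
        violations = validate_batch(batch, scheme)
        traits = [v for v in violations if v["check"] == "trait_mismatch"]
        assert len(traits) == 1 and traits[0]["index"] == 2

    def test_fuzzed_batches_agree_with_pairwise_recheck(self):
        rng = np.random.default_rng(5)
        ds = _cohort(two_rec_cohort(8))
        scheme = SchemeConfig.from_name("neg_sim_age")
        for batch in build_negative_constrained_batches(
                ds, scheme, 4, rng, n_batches=30):
            if rng.random() < 0.5:  # corrupt half the batches
                k = int(rng.integers(len(batch.views)))
                batch.metadata.loc[k, "age_band"] = "corrupted"
            violations = validate_batch(batch, scheme)
            # independent brute-force check over all view pairs
            vals = list(batch.metadata["age_band"])
            brute_bad = any(a != b for a, b in combinations(vals, 2))
            assert bool([v for v in violations
                         if v["check"] == "trait_mismatch"]) == brute_bad


class TestAugmentationBatches:
    def test_views_are_independent_augmentations(self):
        from auscon.augment import MaskSpec, time_mask

        ds = _cohort(two_rec_cohort(10))
        scheme = SchemeConfig.from_name("time_mask")
        m = MaskSpec()
        batch = next(iter(build_unconstrained_batches(
            ds, scheme, 4, np.random.default_rng(0), n_batches=1,
            view_fn=lambda s, r: time_mask(s, m, r))))
        assert len(batch.views) == 8
        for i in range(4):
            a, b = batch.views[i], batch.views[i + 4]
            assert batch.recording_indices[i] == batch.recording_indices[i + 4]
            assert not np.array_equal(a.values, b.values)  # independent draws
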