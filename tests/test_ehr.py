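"""Record cleansing, deduplication, history selection, outcome labeling,
imputation, and split sizing."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edembed import (RejectReason, cleanse_visits, deduplicate_revisits,
                     impute_and_perturb, label_critical_outcome, select_history,
                     split_sizes)
from edembed.ehr import CohortStats, VITAL_FIELDS, assign_splits

from conftest import make_visit


class TestCleanse:
    @pytest.mark.parametrize("kwargs, reason", [
        (dict(sbp=310.0), RejectReason.SBP_GT_300),
        (dict(sbp=80.0, dbp=90.0), RejectReason.DBP_GT_SBP),
        (dict(hr=260.0), RejectReason.HR_GT_250),
        (dict(rr=120.0), RejectReason.RR_GT_100),
        (dict(bt=18.0), RejectReason.BT_OUT_OF_RANGE),
        (dict(bt=49.0), RejectReason.BT_OUT_OF_RANGE),
        (dict(weight=450.0), RejectReason.WT_GT_400),
        (dict(height=260.0), RejectReason.HT_GT_250),
    ])
    def test_threshold_violations_rejected_with_code(self, kwargs, reason):
        _, rejected = cleanse_visits([make_visit(**kwargs)])
        assert [r for _, r in rejected] == [reason]

    def test_missing_chief_complaint_rejected(self):
        _, rejected = cleanse_visits([make_visit(cc="  ")])
        assert rejected[0][1] == RejectReason.MISSING_CC

    def test_all_vitals_missing_is_kept(self):
        kept, rejected = cleanse_visits([make_visit()])
        assert len(kept) == 1 and not rejected

    def test_normal_vitals_kept(self):
        kept, _ = cleanse_visits([make_visit(bt=37.0, hr=80.0)])
        assert len(kept) == 1

    def test_boundary_values_are_legal(self):
        kept, _ = cleanse_visits([make_visit(sbp=300.0, dbp=300.0, hr=250.0,
                                             rr=100.0, bt=48.0, weight=400.0,
                                             height=250.0)])
        assert len(kept) == 1

    def test_partition_and_idempotence(self):
        visits = [make_visit(visit_id=f"v{i}", sbp=s)
                  for i, s in enumerate([120.0, 310.0, None, 90.0])]
        kept, rejected = cleanse_visits(visits)
        assert len(kept) + len(rejected) == len(visits)
        kept2, rejected2 = cleanse_visits(kept)
        assert not rejected2 and [v.visit_id for v in kept2] == [v.visit_id for v in kept]

    def test_order_preserved(self):
        visits = [make_visit(visit_id=f"v{i}") for i in range(5)]
        kept, _ = cleanse_visits(visits)
        assert [v.visit_id for v in kept] == [f"v{i}" for i in range(5)]


class TestDeduplicate:
    def test_keeps_max_revisit_flag_per_account(self):
        visits = [make_visit("v1", account="acctA", flag=0),
                  make_visit("v2", account="acctA", flag=1),
                  make_visit("v3", account="acctB", flag=0)]
        out = deduplicate_revisits(visits)
        assert [(v.account_id, v.revisit_flag) for v in out] == [("acctA", 1), ("acctB", 0)]

    def test_single_visit_unchanged(self):
        v = make_visit("v1")
        assert deduplicate_revisits([v]) == [v]

    def test_five_accounts_three_flags_each(self):
        visits = [make_visit(f"v{a}{f}", account=f"acct{a}", flag=f)
                  for a in range(5) for f in range(3)]
        out = deduplicate_revisits(visits)
        assert len(out) == 5 and all(v.revisit_flag == 2 for v in out)
        assert len({v.account_id for v in out}) == 5

    def test_duplicate_key_raises(self):
        visits = [make_visit("v1", account="a", flag=1),
                  make_visit("v2", account="a", flag=1)]
        with pytest.raises(ValueError, match="DUPLICATE_KEY"):
            deduplicate_revisits(visits)

    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 20)),
                    min_size=1, max_size=30, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_output_accounts_unique(self, pairs):
        visits = [make_visit(f"v{i}", account=f"acct{a}", flag=f)
                  for i, (a, f) in enumerate(pairs)]
        out = deduplicate_revisits(visits)
        accounts = [v.account_id for v in out]
        assert len(accounts) == len(set(accounts)) == len({a for a, _ in pairs})


class TestSelectHistory:
    T0 = datetime(2017, 1, 10)

    def test_strictly_before_triage(self):
        records = [(self.T0 + timedelta(days=d), f"t{d}") for d in (1, 2, 5)]
        assert select_history(records, self.T0 + timedelta(days=3)) == ["t1", "t2"]

    def test_all_future_gives_empty(self):
        records = [(self.T0 + timedelta(days=d), "x") for d in (1, 2)]
        assert select_history(records, self.T0) == []

    def test_boundary_excluded_and_sorted(self):
        rng = np.random.default_rng(0)
        days = rng.permutation(10)
        records = [(self.T0 + timedelta(days=int(d)), f"t{d}") for d in days]
        triage = self.T0 + timedelta(days=4.5)
        expected = [f"t{d}" for d in sorted(int(d) for d in days if d < 4.5)]
        assert select_history(records, triage) == expected
        assert len(expected) == 5


class TestOutcomeLabel:
    def test_icu_within_window(self):
        v = make_visit()
        v.icu_time = v.triage_time + timedelta(days=2)
        assert label_critical_outcome(v) == 1

    def test_death_outside_window(self):
        v = make_visit()
        v.death_time = v.triage_time + timedelta(days=10)
        assert label_critical_outcome(v) == 0

    def test_no_events(self):
        assert label_critical_outcome(make_visit()) == 0

    def test_boundary_inclusive(self):
        v = make_visit()
        v.death_time = v.triage_time + timedelta(days=3)
        assert label_critical_outcome(v) == 1

    def test_event_before_triage_not_counted(self):
        v = make_visit()
        v.icu_time = v.triage_time - timedelta(hours=1)
        assert label_critical_outcome(v) == 0

    def test_nhamcs_mode_ignores_window(self):
        v = make_visit()
        v.death_time = v.triage_time + timedelta(days=30)
        assert label_critical_outcome(v, mode="nhamcs") == 1
        assert label_critical_outcome(v, mode="window") == 0

    @given(st.floats(min_value=0.0, max_value=20.0),
           st.floats(min_value=0.5, max_value=15.0))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_window(self, event_days, window):
        v = make_visit()
        v.icu_time = v.triage_time + timedelta(days=event_days)
        small = label_critical_outcome(v, window_days=window)
        large = label_critical_outcome(v, window_days=window + 5.0)
        assert large >= small


class TestImpute:
    def test_identity_when_all_present_no_noise(self, default_stats):
        v = make_visit(age=30.0, sbp=120.0, dbp=70.0, hr=80.0, spo2=98.0,
                       rr=16.0, bt=36.8, height=170.0, weight=70.0, pain=2.0,
                       gcs_total=15.0, eye=4.0, verbal=5.0, motor=6.0).vitals
        v.gender = "male"
        x = impute_and_perturb(v, default_stats, noise_fraction=0.0)
        expected = [30, 1.0, 120, 70, 80, 98, 16, 36.8, 170, 70, 2, 15, 4, 5, 6]
        assert np.allclose(x, expected)

    def test_missing_field_gets_training_mean(self, default_stats):
        v = make_visit(sbp=120.0).vitals
        x = impute_and_perturb(v, default_stats, noise_fraction=0.0)
        hr_idx = VITAL_FIELDS.index("hr")
        assert x[hr_idx] == pytest.approx(default_stats.means["hr"])
        assert x[VITAL_FIELDS.index("sbp")] == 120.0

    def test_noise_scale_matches_contract(self, default_stats):
        """Monte-Carlo: empirical SD of the perturbation on one field is
        noise_fraction x that field's training SD within 5%."""
        v = make_visit(sbp=120.0, hr=80.0).vitals
        rng = np.random.default_rng(123)
        hr_idx = VITAL_FIELDS.index("hr")
        draws = np.array([impute_and_perturb(v, default_stats, 0.1, rng)[hr_idx]
                          for _ in range(10_000)])
        target = 0.1 * default_stats.sds["hr"]
        assert abs(draws.std() - target) / target < 0.05

    def test_gender_never_perturbed(self, default_stats):
        v = make_visit().vitals
        v.gender = "female"
        rng = np.random.default_rng(0)
        g_idx = VITAL_FIELDS.index("gender")
        for _ in range(50):
            assert impute_and_perturb(v, default_stats, 0.5, rng)[g_idx] == 0.0

    def test_incomplete_stats_raises(self):
        stats = CohortStats(means={"age": 40.0}, sds={"age": 10.0})
        with pytest.raises(ValueError, match="INCOMPLETE_STATS"):
            impute_and_perturb(make_visit().vitals, stats)

    def test_deterministic_given_seed(self, default_stats):
        v = make_visit(sbp=120.0).vitals
        a = impute_and_perturb(v, default_stats, 0.2, np.random.default_rng(9))
        b = impute_and_perturb(v, default_stats, 0.2, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestSplits:
    @pytest.mark.parametrize("n, expected", [
        (1_019_437, (815_550, 101_943, 101_944)),
        (297_508, (238_006, 29_751, 29_751)),
        (10, (8, 1, 1)),
        (0, (0, 0, 0)),
    ])
    def test_published_split_tables(self, n, expected):
        assert tuple(split_sizes(n)) == expected

    @given(st.integers(min_value=0, max_value=10_000_000))
    @settings(deadline=None, max_examples=200)
    def test_sizes_always_partition(self, n):
        s = split_sizes(n)
        assert s.n_train + s.n_val + s.n_test == n
        assert min(s.n_train, s.n_val, s.n_test) >= 0

    def test_assignment_is_seeded_partition(self):
        ids = [f"v{i}" for i in range(1000)]
        m1 = assign_splits(ids, seed=5)
        m2 = assign_splits(ids, seed=5)
        assert m1 == m2
        counts = {k: 0 for k in ("train", "val", "test")}
        for split in m1.values():
            counts[split] += 1
        assert (counts["train"], counts["val"], counts["test"]) == (800, 100, 100)
        assert assign_splits(ids, seed=6) != m1


class TestCsvRoundTrip:
    def test_csv_matches_jsonl_dialect(self, tmp_path):
        from edembed.synthetic import SyntheticConfig, generate_cohort
        from edembed.ehr import visits_from_csv, visits_to_csv

        cohort = generate_cohort(SyntheticConfig(n_visits=40, seed=13, invalid_rate=0.05))
        path = tmp_path / "visits.csv"
        visits_to_csv(cohort.visits, path)
        back = visits_from_csv(path)
        assert len(back) == 40
        for a, b in zip(cohort.visits, back):
            assert a.visit_id == b.visit_id
            assert a.chief_complaint == b.chief_complaint
            assert a.triage_time == b.triage_time
            assert a.history_texts == b.history_texts
            assert a.icu_time == b.icu_time and a.death_time == b.death_time
            assert all(getattr(a.vitals, f) == getattr(b.vitals, f)
                       for f in VITAL_FIELDS)
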