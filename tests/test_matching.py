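"""Elixhauser scoring, covariates, propensity model, greedy caliper matching."""

import warnings

import numpy as np
import pandas as pd
import pytest

from trdclaims.cohort import build_cohort
from trdclaims.config import ELIXHAUSER_CATEGORIES, CodeLists, StudyWindows
from trdclaims.matching import (
    age_group,
    build_covariate_table,
    compute_elixhauser,
    extract_baseline_covariates,
    fit_propensity,
    greedy_match,
    standardized_mean_differences,
    verify_matched_cohort,
)

from .conftest import med, med_frame

CODES = CodeLists()
WINDOWS = StudyWindows()


class TestElixhauser:
    def test_no_claims_scores_zero(self):
        assert compute_elixhauser(med_frame([])) == 0

    def test_every_category_scores_thirty(self):
        claims = med_frame([med(offset=-100, icd=prefixes[0])
                            for prefixes in ELIXHAUSER_CATEGORIES.values()])
        assert compute_elixhauser(claims) == 30

    def test_distinct_categories_counted_once(self):
        # three heart-failure codes + one obesity code -> 2 points
        claims = med_frame([med(offset=-10, icd="4280"), med(offset=-20, icd="42822"),
                            med(offset=-30, icd="4289"), med(offset=-40, icd="27800")])
        assert compute_elixhauser(claims) == 2

    def test_codes_joined_on_one_claim_count(self):
        claims = med_frame([med(offset=-10, icd="4280;27800;49390")])
        assert compute_elixhauser(claims) == 3


class TestCovariates:
    RECORD = dict(patient_id="P1", index_date=__import__("datetime").date(2013, 3, 1),
                  age_at_index=40, sex="female", index_year=2013,
                  diagnosis_category="296.X")

    @pytest.mark.parametrize("age,expected", [(18, "18-24"), (24, "18-24"), (25, "25-34"),
                                              (44, "35-44"), (55, "55-63"), (63, "55-63")])
    def test_age_bins_as_published(self, age, expected):
        assert age_group(age) == expected

    def test_age_outside_range_is_contract_violation(self):
        with pytest.raises(ValueError):
            age_group(64)

    def test_anxiety_flag_only_from_baseline_window(self):
        row = extract_baseline_covariates(
            self.RECORD, med_frame([med(offset=-100, icd="30001")]), CODES, WINDOWS)
        assert row["anxiety"] == 1
        assert row["personality_disorder"] == row["substance_abuse"] == row["ptsd"] == 0
        # 13 months before index: outside the 365-day baseline
        row = extract_baseline_covariates(
            self.RECORD, med_frame([med(offset=-395, icd="30001")]), CODES, WINDOWS)
        assert row["anxiety"] == 0


class TestPropensity:
    def _covariates(self, n, rng):
        return pd.DataFrame({
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age_at_index": rng.integers(18, 64, n),
            "female": rng.integers(0, 2, n),
            "index_year": 2013,
            "diagnosis_category": rng.choice(["296.X", "300.X", "309.X", "311.X"], n),
            "anxiety": rng.integers(0, 2, n),
            "personality_disorder": rng.integers(0, 2, n),
            "substance_abuse": rng.integers(0, 2, n),
            "ptsd": rng.integers(0, 2, n),
            "elixhauser": rng.poisson(1.5, n),
        })

    def test_mean_score_near_prevalence_when_labels_independent(self):
        rng = np.random.default_rng(1)
        cov = self._covariates(4000, rng)
        labels = rng.random(4000) < 0.2
        pm = fit_propensity(cov, pd.Series(labels))
        assert abs(pm.scores.mean() - labels.mean()) < 0.01
        assert ((pm.scores > 0) & (pm.scores < 1)).all()

    def test_identical_covariates_get_identical_scores(self):
        rng = np.random.default_rng(2)
        cov = self._covariates(200, rng)
        cov = pd.concat([cov, cov.assign(patient_id=cov["patient_id"] + "dup")],
                        ignore_index=True)
        labels = pd.Series(rng.random(400) < 0.3)
        pm = fit_propensity(cov, labels)
        np.testing.assert_allclose(pm.scores.iloc[:200].to_numpy(),
                                   pm.scores.iloc[200:].to_numpy(), atol=1e-10)

    def test_saturated_two_by_two_matches_cell_fractions(self):
        """With one varying binary covariate, fitted scores equal the
        hand-counted TRD fraction within each cell (4/10 and 1/10)."""
        rows, labels = [], []
        for i in range(20):
            rows.append(dict(patient_id=f"P{i:02d}", age_at_index=40, female=1,
                             index_year=2013, diagnosis_category="296.X",
                             anxiety=int(i < 10), personality_disorder=0,
                             substance_abuse=0, ptsd=0, elixhauser=0))
            labels.append(int(i < 4 or i == 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pm = fit_propensity(pd.DataFrame(rows), pd.Series(labels))
        np.testing.assert_allclose(pm.scores.iloc[:10], 0.4, atol=1e-6)
        np.testing.assert_allclose(pm.scores.iloc[10:], 0.1, atol=1e-6)

    def test_single_class_rejected(self):
        cov = self._covariates(50, np.random.default_rng(3))
        with pytest.raises(ValueError):
            fit_propensity(cov, pd.Series(np.ones(50, dtype=bool)))


def _scores(pairs):
    s = pd.Series({pid: score for pid, score, _ in pairs}, name="score")
    labels = pd.Series({pid: lab for pid, _, lab in pairs})
    return s, labels


def greedy_oracle(scores: pd.Series, labels: pd.Series, ratio: int, caliper: float):
    """Plain-python restatement of the greedy policy used as an oracle."""
    cases = sorted([p for p in scores.index if labels[p]],
                   key=lambda p: (-scores[p], p))
    controls = {p for p in scores.index if not labels[p]}
    matches, unmatched = [], []
    for case in cases:
        cands = sorted(
            ((abs(scores[c] - scores[case]), c) for c in controls
             if abs(scores[c] - scores[case]) <= caliper + 1e-9))
        take = [c for _, c in cands[:ratio]]
        if not take:
            unmatched.append(case)
            continue
        controls -= set(take)
        matches.append((case, take))
    return matches, unmatched


class TestGreedyMatch:
    def test_oversupplied_case_takes_exactly_ratio_controls(self):
        pairs = [("case", 0.5, True)] + [
            (f"c{i}", 0.5 + 0.0005 * i, False) for i in range(10)]
        s, labels = _scores(pairs)
        mc = greedy_match(s, labels)
        assert len(mc.matches[0][1]) == 4

    def test_control_just_outside_caliper_leaves_case_unmatched(self):
        s, labels = _scores([("case", 0.5, True), ("c", 0.521, False)])
        mc = greedy_match(s, labels)
        assert mc.matches == [] and mc.unmatched_case_ids == ["case"]

    def test_caliper_boundary_inclusive(self):
        s, labels = _scores([("case", 0.5, True), ("c", 0.52, False)])
        mc = greedy_match(s, labels)
        assert mc.matches == [("case", ["c"])]

    def test_competition_resolved_by_processing_order(self):
        # higher-score case processed first takes the single shared control
        s, labels = _scores([("hi", 0.52, True), ("lo", 0.50, True), ("c", 0.51, False)])
        mc = greedy_match(s, labels)
        assert mc.matches == [("hi", ["c"])]
        assert mc.unmatched_case_ids == ["lo"]

    def test_no_controls_leaves_all_cases_unmatched(self):
        s, labels = _scores([("a", 0.4, True), ("b", 0.6, True)])
        mc = greedy_match(s, labels)
        assert mc.unmatched_case_ids == ["b", "a"]  # descending-score order

    def test_matches_brute_force_policy_on_small_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(200):
            n = int(rng.integers(2, 21))
            pairs = [(f"p{i:02d}", float(np.round(rng.random(), 3)),
                      bool(rng.random() < 0.4)) for i in range(n)]
            s, labels = _scores(pairs)
            if labels.all():
                continue
            ratio = int(rng.integers(1, 5))
            caliper = float(rng.choice([0.02, 0.05, 0.2]))
            mc = greedy_match(s, labels, ratio=ratio, caliper=caliper)
            exp_matches, exp_unmatched = greedy_oracle(s, labels, ratio, caliper)
            assert mc.matches == exp_matches, f"trial {trial}"
            assert mc.unmatched_case_ids == exp_unmatched

    def test_invariants_verified_post_hoc(self, small_bundle):
        cohort, _ = build_cohort(small_bundle.patients, small_bundle.pharmacy_claims,
                                 small_bundle.medical_claims, small_bundle.enrollment)
        cohort = cohort.merge(small_bundle.ground_truth[["patient_id", "is_trd"]],
                              on="patient_id")
        cov = build_covariate_table(cohort, small_bundle.medical_claims)
        pm = fit_propensity(cov, cohort["is_trd"])
        labels = pd.Series(cohort["is_trd"].to_numpy(), index=pm.scores.index)
        mc = greedy_match(pm.scores, labels)
        verify_matched_cohort(mc, pm.scores, labels)  # raises on violation
        frame = mc.to_frame()
        assert (frame["pair_distance"] <= mc.caliper + 1e-9).all()
        assert frame["control_id"].is_unique


def test_matching_improves_covariate_balance():
    """With arm-shifted covariates, every propensity covariate's absolute
    standardized mean difference shrinks after matching."""
    from trdclaims import SimulationConfig, generate_claims
    bundle = generate_claims(SimulationConfig(n_patients=3500, seed=99))
    cohort, _ = build_cohort(bundle.patients, bundle.pharmacy_claims,
                             bundle.medical_claims, bundle.enrollment)
    cohort = cohort.merge(bundle.ground_truth[["patient_id", "is_trd"]], on="patient_id")
    cov = build_covariate_table(cohort, bundle.medical_claims)
    pm = fit_propensity(cov, cohort["is_trd"])
    labels = pd.Series(cohort["is_trd"].to_numpy(), index=pm.scores.index)
    pre = standardized_mean_differences(cov, cohort["is_trd"])
    mc = greedy_match(pm.scores, labels)
    keep = set(mc.case_ids) | set(mc.control_ids)
    mask = cov["patient_id"].isin(keep).to_numpy()
    post = standardized_mean_differences(cov[mask], cohort["is_trd"][mask])
    confounded = ["age_at_index", "female", "anxiety", "personality_disorder",
                  "substance_abuse", "ptsd", "elixhauser"]
    for col in confounded:
        assert post[col] < pre[col], (col, pre[col], post[col])
    # diagnosis-category dummies were not arm-shifted; compare in aggregate
    assert post.mean() < pre.mean()
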