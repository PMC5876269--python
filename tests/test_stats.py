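"""Classification and nonparametric statistics against enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cetcem as c
from cetcem.errors import CohortValidationError, DegenerateTestError
from cetcem.stats import kappa_from_ratings, validate_cohort


class TestClassifyExtruded:
    @pytest.mark.parametrize(
        "value, expected",
        [(3.1, True), (2.2, False), (3.0, True), (-0.5, False), (4.8, True)],
    )
    def test_absolute_threshold(self, value, expected):
        assert c.classify_extruded(value) is expected

    def test_relative_criterion_optional(self):
        assert not c.classify_extruded(2.5)
        assert c.classify_extruded(2.5, meniscal_width_mm=8.0)  # 30% of 8 = 2.4

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            c.classify_extruded(float("nan"))


def _wilcoxon_enumeration(diffs):
    """Brute-force two-sided exact p over all sign assignments."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_three_diffs_exact_quarter(self):
        w, p = c.wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert w == 6.0
        assert p == pytest.approx(0.25, abs=1e-12)

    def test_single_nonzero_pair_handled(self):
        w, p = c.wilcoxon_signed_rank([1.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert w == 1.0
        assert 0 < p <= 1

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            c.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _w1, p1 = c.wilcoxon_signed_rank(a, b)
        _w2, p2 = c.wilcoxon_signed_rank(b, a)
        assert p1 == pytest.approx(p2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        a = np.round(rng.normal(size=n), 1)
        b = np.round(rng.normal(size=n), 1)
        if np.all(a == b):
            return
        w, p = c.wilcoxon_signed_rank(a, b)
        w_ref, p_ref = _wilcoxon_enumeration(a - b)
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.3, 1.0, size=60)
        b = np.zeros(60)
        _w, p = c.wilcoxon_signed_rank(a, b)
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(a, b, correction=False, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestFriedman:
    def test_unanimous_rankings_closed_form(self):
        # 4 blocks always ranked (1,2,3): chi2 = 2n = 8
        m = np.array([[1.0, 2.0, 3.0]] * 4) + np.arange(4)[:, None]
        chi2, p = c.friedman_test(m)
        assert chi2 == pytest.approx(8.0, abs=1e-12)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(8, 3))
        chi2a, _ = c.friedman_test(m)
        chi2b, _ = c.friedman_test(m[:, [2, 0, 1]])
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_all_equal_values_give_zero(self):
        chi2, p = c.friedman_test(np.full((5, 3), 7.0))
        assert chi2 == 0.0
        assert p == 1.0

    def test_too_small_rejected(self):
        with pytest.raises(DegenerateTestError):
            c.friedman_test(np.ones((2, 3)))


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert c.spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)
        assert c.spearman_rho(x, -np.asarray(x))[0] == pytest.approx(-1.0)

    def test_rank_formula_worked_example(self):
        # sum(d^2) = 4, n = 5: rho = 1 - 6*4/(5*24) = 0.8
        rho, _p = c.spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(DegenerateTestError):
            c.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKappa:
    def test_identical_mixed_ratings_give_one(self):
        k = c.cohen_kappa([1, 1, 0, 0, 1], [1, 1, 0, 0, 1])
        assert k.kappa == pytest.approx(1.0)

    def test_worked_five_item_table(self):
        # p_o = 0.8, p_e = 0.48 -> kappa = 0.32/0.52 = 0.6154
        k = c.cohen_kappa([1, 1, 0, 0, 1], [1, 0, 0, 0, 1])
        assert k.kappa == pytest.approx(0.6154, abs=1e-4)
        assert k.p_observed == pytest.approx(0.8)
        assert k.p_expected == pytest.approx(0.48)
        assert k.se > 0

    def test_chance_level_agreement_near_zero(self):
        a = [1, 1, 0, 0] * 3
        b = [1, 0, 1, 0] * 3
        k = c.cohen_kappa(a, b)
        assert k.kappa == pytest.approx(0.0, abs=1e-12)

    def test_identical_constant_ratings_undefined(self):
        k = c.cohen_kappa([1, 1, 1], [1, 1, 1])
        assert k.undefined
        assert np.isnan(k.kappa)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=30))
    def test_kappa_never_exceeds_one(self, pairs):
        a = [int(x) for x, _ in pairs]
        b = [int(y) for _, y in pairs]
        k = c.cohen_kappa(a, b)
        if not k.undefined:
            assert k.kappa <= 1.0 + 1e-12


def _toy_cohort():
    rows = []
    values = {
        "CETCEM": [(3.1, 26.0), (2.5, 30.0), (4.0, 40.0)],
        "CoronalSlices": [(4.8, 10.0), (4.0, 12.0), (5.5, 9.0)],
        "BonyLandmarks": [(2.2, 30.0), (1.8, 31.0), (3.5, 30.0)],
    }
    for method, vals in values.items():
        for i, (e, loc) in enumerate(vals):
            rows.append(
                {
                    "knee_id": f"k{i}",
                    "method": method,
                    "max_extrusion_mm": e,
                    "location_ap_mm": loc,
                    "location_pct": 100 * loc / 52.9,
                    "extruded": e >= 3.0,
                }
            )
    return pd.DataFrame(rows)


class TestCohortAnalysis:
    def test_hand_computed_summaries(self):
        rep = c.run_cohort_analysis(_toy_cohort())
        cet = rep.per_method["CETCEM"]
        assert cet["max_extrusion_median"] == pytest.approx(3.1)
        assert cet["max_extrusion_mean"] == pytest.approx((3.1 + 2.5 + 4.0) / 3)
        assert cet["max_extrusion_sd"] == pytest.approx(np.std([3.1, 2.5, 4.0], ddof=1))
        assert cet["n_extruded"] == 2

    def test_identical_methods_give_null_tests(self):
        df = _toy_cohort()
        base = df[df["method"] == "CETCEM"][["knee_id", "max_extrusion_mm", "location_ap_mm"]]
        rows = []
        for method in c.METHODS:
            for _, r in base.iterrows():
                rows.append(
                    {
                        "knee_id": r["knee_id"],
                        "method": method,
                        "max_extrusion_mm": r["max_extrusion_mm"],
                        "location_ap_mm": r["location_ap_mm"],
                        "location_pct": 50.0,
                        "extruded": True,
                    }
                )
        rep = c.run_cohort_analysis(pd.DataFrame(rows))
        assert rep.friedman_extrusion[0] == 0.0
        for rho, _p in rep.spearman_extrusion.values():
            assert rho == pytest.approx(1.0)

    def test_missing_method_coverage_names_knee(self):
        df = _toy_cohort()
        df = df[~((df["knee_id"] == "k1") & (df["method"] == "CETCEM"))]
        with pytest.raises(CohortValidationError, match="k1"):
            validate_cohort(df)

    def test_missing_column_rejected(self):
        with pytest.raises(CohortValidationError, match="columns"):
            validate_cohort(_toy_cohort().drop(columns=["extruded"]))

    def test_ratings_kappas(self):
        rows = []
        calls = {"k0": True, "k1": False, "k2": True, "k3": False}
        for knee, call in calls.items():
            rows.append({"knee_id": knee, "rater": "A", "reading": 1, "extruded": call})
            rows.append({"knee_id": knee, "rater": "A", "reading": 2, "extruded": call})
            rows.append(
                {"knee_id": knee, "rater": "B", "reading": 1, "extruded": call if knee != "k2" else not call}
            )
        out = kappa_from_ratings(pd.DataFrame(rows))
        assert out["intraobserver_A"]["kappa"] == pytest.approx(1.0)
        assert out["interobserver"]["kappa"] < 1.0
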