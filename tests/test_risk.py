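"""Signal labeling, quadrant classification, risk scoring, driver filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sefrisk import (
    apply_filter,
    assess_correlation,
    assess_risk,
    classify_quadrant,
    generate_scenario,
    label_signal,
    run_assessment,
    simulate_tree,
)
from sefrisk.risk import CorrelationAssessment, RunConfig
from sefrisk.signal import DegenerateInputError
from sefrisk.synthetic import ScenarioSpec

# the seven printed case-study (value, kind, label) pairs
CASE_STUDY_LABELS = [
    (0.32, "lambda", "moderate"),   # Sheffield decomposability
    (0.70, "lambda", "strong"),     # Argentina decomposability
    (0.22, "lambda", "weak"),       # bushmeat harvest rate
    (1.00, "lambda", "strong"),     # long-distance dispersal / both SRF proxies
    (0.39, "lambda", "moderate"),   # overall seed dispersal
    (0.13, "one_minus_d", "none"),  # Sheffield seed-bank persistence
    (0.25, "one_minus_d", "moderate"),  # Argentina seed-bank persistence
]

# the five case-study rows: (sef stat/kind, srf stat/kind,
# phylo r2, nonphylo r2, sign) -> printed risk
CASE_STUDY_ROWS = [
    ((0.32, "lambda"), (0.13, "one_minus_d"), 0.0005, 0.0005, -1, "very_low"),
    ((0.70, "lambda"), (0.25, "one_minus_d"), 0.0005, 0.027, -1, "low"),
    ((0.22, "lambda"), (1.00, "lambda"), 0.0005, 0.018, -1, "low"),
    ((1.00, "lambda"), (1.00, "lambda"), 0.42, 0.57, -1, "high"),
    ((0.39, "lambda"), (1.00, "lambda"), 0.001, 0.02, 1, "very_low"),
]


class TestLabelSignal:
    @pytest.mark.parametrize("value,kind,expected", CASE_STUDY_LABELS)
    def test_case_study_labels(self, value, kind, expected):
        assert label_signal(value, kind).level == expected

    def test_lambda_band_edges(self):
        assert label_signal(0.0, "lambda").level == "none"
        assert label_signal(0.15, "lambda").level == "weak"
        assert label_signal(0.30, "lambda").level == "moderate"
        assert label_signal(0.60, "lambda").level == "strong"

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            label_signal(1.2, "lambda")
        with pytest.raises(ValueError):
            label_signal(-0.1, "one_minus_d")

    def test_unknown_kind_error(self):
        with pytest.raises(ValueError):
            label_signal(0.5, "blomberg_k")


class TestClassifyQuadrant:
    @pytest.mark.parametrize(
        "sef,srf,expected",
        [
            ("none", "none", "A"),
            ("weak", "weak", "A"),
            ("strong", "none", "B"),
            ("moderate", "weak", "B"),
            ("none", "strong", "C"),
            ("strong", "strong", "D"),
            ("moderate", "moderate", "D"),
        ],
    )
    def test_dichotomization(self, sef, srf, expected):
        sl = label_signal({"none": 0.05, "weak": 0.2, "moderate": 0.4,
                           "strong": 0.9}[sef], "lambda")
        rl = label_signal({"none": 0.05, "weak": 0.2, "moderate": 0.4,
                           "strong": 0.9}[srf], "lambda")
        assert sl.level == sef and rl.level == srf
        assert classify_quadrant(sl, rl) == expected


class TestAssessRisk:
    @pytest.mark.parametrize("sef,srf,pr2,nr2,sign,expected", CASE_STUDY_ROWS)
    def test_case_study_risk_labels(self, sef, srf, pr2, nr2, sign, expected):
        quadrant = classify_quadrant(
            label_signal(*sef), label_signal(*srf)
        )
        corr = CorrelationAssessment(
            phylo_r2=pr2, nonphylo_r2=nr2, sign=sign, quadratic_p=0.5
        )
        risk, max_concern, _ = assess_risk(quadrant, corr)
        assert risk == expected
        assert max_concern == (expected == "high" and quadrant == "D")

    def test_strong_negative_outside_d_is_high_without_flag(self):
        corr = CorrelationAssessment(0.4, 0.5, -1, 0.5)
        risk, max_concern, _ = assess_risk("B", corr)
        assert risk == "high" and not max_concern

    def test_strong_positive_flagged_very_low(self):
        corr = CorrelationAssessment(0.5, 0.6, 1, 0.5)
        risk, _, notes = assess_risk("D", corr)
        assert risk == "very_low"
        assert any("tolerant" in n for n in notes)


class TestAssessCorrelation:
    def test_perfect_negative(self, yule32):
        from sefrisk import simulate_continuous

        sef = simulate_continuous(yule32, 0.5, seed=1)
        res = assess_correlation(yule32, sef, -sef)
        assert res.nonphylo_r2 == pytest.approx(1.0, abs=1e-10)
        assert res.phylo_r2 == pytest.approx(1.0, abs=1e-8)
        assert res.sign == -1

    def test_permuted_null_expectation(self, rng):
        # E[r2] under independence is 1/(n-1)
        n = 40
        star_tree = simulate_tree(n, seed=2)
        r2s = []
        for _ in range(200):
            sef = rng.standard_normal(n)
            srf = rng.standard_normal(n)
            res = assess_correlation(star_tree, sef, srf)
            r2s.append(res.nonphylo_r2)
        assert np.mean(r2s) == pytest.approx(1.0 / (n - 1), abs=0.01)

    def test_target_rho_recovered(self):
        # rho = -0.75 so population r2 = 0.5625
        r2s = []
        for rep in range(60):
            tree = simulate_tree(100, seed=3000 + rep)
            spec = ScenarioSpec("A", n_tips=100, rho=-0.75, seed=rep)
            from sefrisk import simulate_sef_srf

            sef, srf = simulate_sef_srf(tree, spec)
            res = assess_correlation(tree, sef, srf)
            r2s.append(res.nonphylo_r2)
        assert 0.45 <= np.mean(r2s) <= 0.65

    def test_constant_input_error(self, yule32, rng):
        with pytest.raises(DegenerateInputError):
            assess_correlation(yule32, np.ones(32), rng.standard_normal(32))


class TestApplyFilter:
    def test_quantile_zero_is_identity(self, yule32, rng):
        sef = rng.standard_normal(32)
        srf = rng.standard_normal(32)
        res = apply_filter(sef, srf, 0.0, yule32)
        assert len(res.survivors) == 32
        assert res.sef_after == res.sef_before
        assert res.pd_retained_fraction == pytest.approx(1.0)

    def test_hand_example_perfect_negative_ranks(self):
        from sefrisk import read_newick

        labels = list("ABCDEFGH")
        tree = read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")
        sef = np.array([8.0, 7, 6, 5, 4, 3, 2, 1])
        srf = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        res = apply_filter(sef, srf, 0.5, tree, labels)
        assert sorted(res.survivors) == ["E", "F", "G", "H"]
        assert res.sef_before.mean == pytest.approx(4.5)
        assert res.sef_after.mean == pytest.approx(2.5)

    @pytest.mark.parametrize("q", [0.1, 0.25, 0.5, 0.8])
    def test_survivor_count_without_ties(self, yule32, rng, q):
        sef = rng.standard_normal(32)
        srf = rng.permutation(np.arange(32.0))  # distinct SRF values
        res = apply_filter(sef, srf, q, yule32)
        assert len(res.survivors) == int(np.ceil(32 * (1 - q)))
        assert res.sef_after.min >= res.sef_before.min
        assert res.sef_after.max <= res.sef_before.max
        assert 0.0 < res.pd_retained_fraction <= 1.0

    def test_ties_all_survive(self, yule32):
        sef = np.arange(32.0)
        srf = np.repeat([0.0, 1.0], 16)
        res = apply_filter(sef, srf, 0.5, yule32)
        # cut value 0.0 has 16 tied species: everyone survives
        assert len(res.survivors) == 32
        assert res.n_tied_at_cut == 16

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        q=st.floats(0.0, 0.97, allow_nan=False),
    )
    def test_survivor_count_property(self, seed, q):
        # distinct SRF values: survivor count is exactly ceil(n * (1 - q))
        tree = simulate_tree(24, seed=3)
        rng = np.random.default_rng(seed)
        sef = rng.standard_normal(24)
        srf = rng.permutation(np.arange(24.0))
        res = apply_filter(sef, srf, q, tree)
        assert len(res.survivors) == int(np.ceil(24 * (1 - q)))
        assert 0.0 < res.pd_retained_fraction <= 1.0

    def test_quantile_domain_error(self, yule32, rng):
        with pytest.raises(ValueError):
            apply_filter(rng.standard_normal(32), rng.standard_normal(32),
                         1.0, yule32)

    def test_null_filter_centered(self, rng):
        # SEF independent of SRF: after-mean minus before-mean centered on 0
        deltas = []
        for rep in range(100):
            tree = simulate_tree(64, seed=4000 + rep)
            sef = rng.standard_normal(64)
            srf = rng.standard_normal(64)
            res = apply_filter(sef, srf, 0.5, tree)
            deltas.append(res.sef_after.mean - res.sef_before.mean)
        assert abs(np.mean(deltas)) < 0.06


class TestRunAssessment:
    def test_quadrant_a_very_low(self):
        ds = generate_scenario(ScenarioSpec("A", n_tips=128, rho=0.0, seed=5))
        report = run_assessment(ds.tree, ds, RunConfig(seed=5))
        assert report.assessment.quadrant == "A"
        assert report.assessment.risk == "very_low"

    def test_quadrant_d_maximum_concern(self):
        ds = generate_scenario(ScenarioSpec("D", n_tips=128, rho=-0.9, seed=6))
        report = run_assessment(ds.tree, ds, RunConfig(seed=6))
        assert report.assessment.quadrant == "D"
        assert report.assessment.risk == "high"
        assert report.assessment.maximum_concern

    def test_missing_srf_role_error(self):
        ds = generate_scenario(ScenarioSpec("A", n_tips=16, seed=7))
        ds.roles = {"sef": "sef"}
        with pytest.raises(ValueError, match="srf"):
            run_assessment(ds.tree, ds, RunConfig(seed=7))

    def test_label_mismatch_without_prune_errors(self):
        from sefrisk.phylo_core import PhylogenyError

        ds = generate_scenario(ScenarioSpec("A", n_tips=16, seed=8))
        ds.table.index = [f"x{i}" for i in range(16)]
        with pytest.raises(PhylogenyError, match="differ"):
            run_assessment(ds.tree, ds, RunConfig(seed=8))

    def test_prune_intersects(self):
        ds = generate_scenario(ScenarioSpec("B", n_tips=32, seed=9))
        ds.table = ds.table.iloc[:24]
        report = run_assessment(ds.tree, ds, RunConfig(seed=9, prune=True))
        assert report.filter_result.sef_before.n == 24

    def test_binary_srf_uses_one_minus_d(self):
        from sefrisk import simulate_binary_threshold
        import pandas as pd

        tree = simulate_tree(64, seed=10)
        sef = np.random.default_rng(1).standard_normal(64)
        srf = simulate_binary_threshold(tree, 0.95, 0.5, seed=11)
        table = pd.DataFrame({"sef": sef, "srf": srf}, index=tree.tip_labels)

        class T:
            data = table
            roles = {"sef": "sef", "srf": "srf"}

        report = run_assessment(tree, T(), RunConfig(seed=12, n_perm=200))
        assert report.assessment.srf_label.statistic_kind == "one_minus_d"
        assert report.assessment.srf_label.high_signal
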