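"""Synthetic two-condition IAT experiment generator."""

import math

import numpy as np
import pandas as pd
import pytest

from cttpower import (
    ConditionSpec,
    DegenerateDataError,
    TrialTable,
    default_condition_specs,
    full_scores,
    generate_experiment,
    moment_match,
    welch_from_scores,
)


class TestConditionSpec:
    def test_defaults_reproduce_study_design(self):
        c1, c2 = default_condition_specs()
        assert (c1.n, c2.n) == (30, 30)
        assert (c1.sigma_X2, c1.rho) == (0.31, 0.92)
        assert (c2.sigma_X2, c2.rho) == (0.05, 0.57)
        assert c1.n_trials == 40
        assert c1.sigma_E2 == pytest.approx(0.31 * 0.08)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_X2": 0.0},
            {"rho": 1.2},
            {"rho": -0.1},
            {"n": 1},
            {"trials_per_block": 0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(label="c", mu=0.0, sigma_X2=0.3, rho=0.9)
        with pytest.raises(ValueError):
            ConditionSpec(**{**base, **kwargs})


class TestGenerateExperiment:
    def test_structure(self, default_table):
        d = default_table.data
        assert set(d.columns) >= {"participant_id", "condition", "block", "trial_index", "score"}
        assert d["participant_id"].nunique() == 60
        counts = d.groupby("participant_id")["score"].size()
        assert (counts == 40).all()
        per_block = d.groupby(["participant_id", "block"])["score"].size()
        assert (per_block == 20).all()

    def test_same_seed_identical_table(self):
        a = generate_experiment(seed=5)
        b = generate_experiment(seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_perfect_reliability_gives_constant_trials(self):
        spec = ConditionSpec(label="c", mu=0.3, sigma_X2=0.2, rho=1.0, n=5)
        table = generate_experiment([spec], seed=1)
        spread = table.data.groupby("participant_id")["score"].std()
        assert np.allclose(spread, 0.0)

    def test_sample_means_satisfy_clt_bound_across_seeds(self):
        """Sample full-score means stay within 3 sigma_X/sqrt(n) of mu
        for nearly all seeds (a ~99.7% event per condition)."""
        hits = 0
        total = 0
        for seed in range(100):
            table = generate_experiment(seed=seed)
            fs = full_scores(table)
            for spec in table.specs:
                m = fs.loc[fs["condition"] == spec.label, "score"].mean()
                bound = 3 * math.sqrt(spec.sigma_X2 / spec.n)
                total += 1
                hits += abs(m - spec.mu) <= bound
        assert hits / total >= 0.97

    def test_full_score_variance_calibration(self):
        """Mean sample full-score variance over replicates tracks sigma_X2."""
        var1, var2 = [], []
        for seed in range(300):
            fs = full_scores(generate_experiment(seed=10_000 + seed))
            g = fs.groupby("condition")["score"].var(ddof=1)
            var1.append(g["attitude_irrelevant"])
            var2.append(g["attitude_relevant"])
        assert np.mean(var1) == pytest.approx(0.31, rel=0.05)
        assert np.mean(var2) == pytest.approx(0.05, rel=0.05)


class TestFullScores:
    def test_constant_scores(self):
        d = pd.DataFrame(
            {
                "participant_id": [0] * 4 + [1] * 4,
                "condition": "c",
                "block": ["practice", "practice", "test", "test"] * 2,
                "trial_index": [0, 1, 2, 3] * 2,
                "score": 0.5,
            }
        )
        fs = full_scores(TrialTable(data=d))
        assert (fs["score"] == 0.5).all()

    def test_two_trial_mean(self):
        d = pd.DataFrame(
            {
                "participant_id": [0, 0, 1, 1],
                "condition": "c",
                "block": ["practice", "test"] * 2,
                "trial_index": [0, 1, 0, 1],
                "score": [0.0, 1.0, 2.0, 4.0],
            }
        )
        fs = full_scores(TrialTable(data=d))
        assert list(fs["score"]) == [0.5, 3.0]


class TestTrialTableValidation:
    def test_unequal_trial_counts_rejected(self):
        d = pd.DataFrame(
            {
                "participant_id": [0, 0, 1, 1, 1, 1],
                "condition": "c",
                "block": "practice",
                "trial_index": [0, 1, 0, 1, 2, 3],
                "score": 0.0,
            }
        )
        with pytest.raises(ValueError, match="same trial count"):
            TrialTable(data=d)

    def test_odd_trial_count_rejected(self):
        d = pd.DataFrame(
            {
                "participant_id": [0, 0, 0],
                "condition": "c",
                "block": "practice",
                "trial_index": [0, 1, 2],
                "score": 0.0,
            }
        )
        with pytest.raises(ValueError, match="even"):
            TrialTable(data=d)

    def test_csv_round_trip(self, tmp_path, default_table):
        path = tmp_path / "trials.csv"
        default_table.to_csv(path)
        back = TrialTable.from_csv(path)
        # CSV serializes floats through decimal text, so allow last-ulp drift
        pd.testing.assert_frame_equal(
            back.data, default_table.data, check_dtype=False, rtol=1e-12
        )


class TestMomentMatch:
    def test_exact_sample_moments(self, matched_table):
        fs = full_scores(matched_table)
        g = fs.groupby("condition")["score"]
        assert g.mean()["attitude_irrelevant"] == pytest.approx(-0.25, abs=1e-10)
        assert g.std(ddof=1)["attitude_irrelevant"] == pytest.approx(0.55, abs=1e-10)
        assert g.mean()["attitude_relevant"] == pytest.approx(0.68, abs=1e-10)
        assert g.std(ddof=1)["attitude_relevant"] == pytest.approx(0.22, abs=1e-10)

    def test_identity_when_targets_equal_current_moments(self, default_table):
        fs = full_scores(default_table)
        g = fs.groupby("condition")["score"]
        targets = {
            c: (float(g.mean()[c]), float(g.std(ddof=1)[c])) for c in g.mean().index
        }
        same = moment_match(default_table, targets)
        pd.testing.assert_frame_equal(same.data, default_table.data, atol=1e-12, rtol=0)

    def test_welch_on_matched_defaults(self, matched_table):
        """The matched moments imply t = 8.60 on 38.05 Welch df."""
        fs = full_scores(matched_table)
        res = welch_from_scores(
            fs.loc[fs["condition"] == "attitude_irrelevant", "score"],
            fs.loc[fs["condition"] == "attitude_relevant", "score"],
        )
        assert res.t == pytest.approx(8.599, abs=0.001)
        assert res.df == pytest.approx(38.048, abs=0.001)
        assert res.p < 0.001

    def test_degenerate_condition_rejected(self):
        d = pd.DataFrame(
            {
                "participant_id": [0, 0, 1, 1],
                "condition": "c",
                "block": ["practice", "test"] * 2,
                "trial_index": [0, 1, 0, 1],
                "score": 1.0,
            }
        )
        with pytest.raises(DegenerateDataError):
            moment_match(TrialTable(data=d), {"c": (0.0, 1.0)})
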