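"""Treatment-cascade tests, including a naive brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_trials
from ddmtrain import (
    DataTreatment,
    TreatmentConfig,
    filter_participants,
    filter_sessions,
    post_error_filter,
    run_treatment,
    trim_rts,
)


def make_stratum(rts, correct=True):
    n = len(rts)
    return pd.DataFrame({
        "participant": "p1", "session": 1, "task": "face",
        "trial": np.arange(1, n + 1), "is_match": True, "response": "match",
        "correct": correct, "rt_ms": np.asarray(rts, dtype=float),
    })


class TestTrimRTs:
    def test_hand_computed_mad_threshold(self):
        # median 350, raw MAD 50, scaled MAD 74.13, cut 535.325
        out = trim_rts(make_stratum([300, 320, 350, 400, 2000]))
        assert sorted(out["rt_ms"]) == [300, 320, 350, 400]

    def test_floor_always_removes_fast_guesses(self):
        out = trim_rts(make_stratum([240, 400, 420, 440]))
        assert 240 not in out["rt_ms"].values

    def test_identical_rts_all_retained(self):
        out = trim_rts(make_stratum([400] * 7))
        assert len(out) == 7

    def test_exactly_at_threshold_retained(self):
        # median 400, raw MAD 50 -> cut = 400 + 2.5 * 74.13 = 585.325
        df = make_stratum([350, 380, 400, 450, 585.325])
        out = trim_rts(df)
        assert 585.325 in out["rt_ms"].values

    def test_empty_and_single_trial_groups(self):
        assert len(trim_rts(make_stratum([]))) == 0
        assert len(trim_rts(make_stratum([500]))) == 1

    def test_unscaled_mad_variant(self):
        cfg = TreatmentConfig(mad_scale_constant=1.0)
        # cut = 350 + 2.5 * 50 = 475: the 400 survives, 500 does not
        out = trim_rts(make_stratum([300, 320, 350, 400, 500]), cfg)
        assert sorted(out["rt_ms"]) == [300, 320, 350, 400]

    def test_sd_rule_variant(self):
        cfg = TreatmentConfig(upper_rule="sd")
        rts = [300, 320, 350, 400, 2000]
        cut = np.mean(rts) + 2.0 * np.std(rts, ddof=1)
        out = trim_rts(make_stratum(rts), cfg)
        assert sorted(out["rt_ms"]) == sorted([r for r in rts if r <= cut])


class TestPostErrorFilter:
    def test_removes_trials_after_errors(self):
        df = make_stratum([400] * 6, correct=True)
        df["correct"] = [True, False, True, True, False, True]
        out = post_error_filter(df)
        assert list(out["trial"]) == [1, 2, 4, 5]  # trials 3 and 6 removed

    def test_all_correct_unchanged(self):
        df = make_stratum([400] * 5)
        assert len(post_error_filter(df)) == 5

    def test_first_trial_never_removed(self):
        df = make_stratum([400] * 3)
        df["correct"] = [False, False, True]
        out = post_error_filter(df)
        assert 1 in out["trial"].values

    def test_nonincreasing_trial_indices_rejected(self):
        df = make_stratum([400] * 3)
        df["trial"] = [1, 1, 2]
        with pytest.raises(ValueError):
            post_error_filter(df)


class TestSessionAndParticipantFilters:
    def _cell(self, participant, session, n, n_errors, task="face"):
        df = make_stratum([500] * n)
        df["participant"] = participant
        df["session"] = session
        df["task"] = task
        df["correct"] = [False] * n_errors + [True] * (n - n_errors)
        df["trial"] = np.arange(1, n + 1)
        return df

    def test_min_trials_boundary(self):
        cfg = TreatmentConfig()
        small = self._cell("p1", 1, 124, 10)
        exact = self._cell("p1", 2, 125, 10)
        out = filter_sessions(pd.concat([small, exact]), cfg, stage="min_trials")
        assert set(out["session"]) == {2}

    def test_low_error_sessions_excluded(self):
        cfg = TreatmentConfig()
        low = self._cell("p1", 1, 500, 10)    # 2% errors
        ok = self._cell("p1", 2, 200, 10)     # 5% errors
        out = filter_sessions(pd.concat([low, ok]), cfg, stage="response_type")
        assert set(out["session"]) == {2}

    def test_participant_session_count_boundary(self):
        cfg = TreatmentConfig()
        nine = pd.concat([self._cell("p1", s, 130, 10) for s in range(1, 10)])
        ten = pd.concat([self._cell("p2", s, 130, 10) for s in range(1, 11)])
        out = filter_participants(pd.concat([nine, ten]), cfg)
        assert set(out["participant"]) == {"p2"}

    def test_participant_filter_is_per_task(self):
        cfg = TreatmentConfig(min_sessions_per_participant=2)
        face = pd.concat([self._cell("p1", s, 130, 10, "face") for s in (1, 2)])
        digit = self._cell("p1", 1, 130, 10, "digit")
        out = filter_participants(pd.concat([face, digit]), cfg)
        assert set(out["task"]) == {"face"}

    def test_complete_dataset_nobody_removed(self):
        cfg = TreatmentConfig(min_sessions_per_participant=3)
        full = pd.concat([
            self._cell(p, s, 130, 10) for p in ("p1", "p2") for s in (1, 2, 3)
        ])
        assert len(filter_participants(full, cfg)) == len(full)


def brute_force_treatment(trials: pd.DataFrame, config: TreatmentConfig) -> pd.DataFrame:
    """Naive-loop re-implementation of the cascade (the independent oracle)."""
    rows = []
    if config.drop_post_error:
        for _, cell in trials.groupby(["task", "participant", "session"]):
            cell = cell.sort_values("trial")
            prev_correct = True
            for _, row in cell.iterrows():
                if prev_correct:
                    rows.append(row)
                prev_correct = bool(row["correct"])
        trials = pd.DataFrame(rows)
        rows = []
    # stage 1: trimming per stratum
    for _, grp in trials.groupby(["task", "participant", "session", "correct"]):
        kept = grp[grp["rt_ms"] >= config.rt_floor_ms]
        if len(kept) == 0:
            continue
        med = float(np.median(kept["rt_ms"]))
        mad = float(np.median(np.abs(kept["rt_ms"] - med)))
        cut = med + config.mad_multiplier * config.mad_scale_constant * mad
        for _, row in kept.iterrows():
            if row["rt_ms"] <= cut:
                rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    # stage 2 + 3: session filters
    keep_cells = []
    for key, cell in df.groupby(["task", "participant", "session"]):
        if len(cell) < config.min_trials_per_session:
            continue
        frac = cell["correct"].mean()
        if min(frac, 1 - frac) < config.min_response_type_fraction:
            continue
        keep_cells.append(key)
    df = df[df.set_index(["task", "participant", "session"]).index.isin(keep_cells)]
    # stage 4: participant filter per task
    keep = []
    for (task, participant), sub in df.groupby(["task", "participant"]):
        n_sessions = sub["session"].nunique()
        if n_sessions >= config.min_sessions_per_participant:
            keep.append((task, participant))
    return df[df.set_index(["task", "participant"]).index.isin(keep)]


class TestCascadeEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("drop_post_error", [False, True])
    def test_matches_brute_force(self, seed, drop_post_error):
        """Vectorized cascade == naive loops on random <=2000-trial datasets."""
        rng = np.random.default_rng(seed)
        trials = random_trials(rng, int(rng.integers(500, 2000)))
        cfg = TreatmentConfig(
            min_trials_per_session=30, min_sessions_per_participant=2,
            drop_post_error=drop_post_error,
        )
        clean, _ = run_treatment(trials, cfg)
        oracle = brute_force_treatment(trials, cfg)
        key = ["task", "participant", "session", "trial"]
        got = set(map(tuple, clean[key].itertuples(index=False)))
        want = set(map(tuple, oracle[key].itertuples(index=False)))
        assert got == want


class TestRunTreatment:
    def test_report_percentages_nonincreasing(self, tiny_study, tiny_treatment_config):
        trials, _ = tiny_study
        _, report = run_treatment(trials, tiny_treatment_config)
        for task, stages in report.pct_remaining.items():
            vals = list(stages.values())
            assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_report_counts_consistent_with_clean_data(self, tiny_study, tiny_treatment_config):
        trials, _ = tiny_study
        clean, report = run_treatment(trials, tiny_treatment_config)
        for task in report.post:
            sub = clean[clean["task"] == task]
            assert report.post[task]["trials"] == len(sub)
            assert report.post[task]["participants"] == sub["participant"].nunique()

    def test_empty_dataset(self):
        empty = make_stratum([]).iloc[0:0]
        clean, report = run_treatment(empty)
        assert len(clean) == 0
        assert report.recorded == {}

    def test_malformed_rt_raises_with_context(self):
        df = make_stratum([400, 500])
        df.loc[1, "rt_ms"] = -10
        with pytest.raises(ValueError, match="row"):
            run_treatment(df)

    def test_order_sensitivity_of_stages(self):
        """Session filtering before trimming changes the outcome.

        A session with exactly 125 raw trials, 5 of them slow
        contaminants: trimming first leaves 120 < 125 so the session is
        excluded; filtering on raw counts first would keep it.
        """
        rng = np.random.default_rng(8)
        good = make_stratum(rng.uniform(400, 600, 120))
        good.loc[good.index[:10], "correct"] = False  # keep error rate above 4%
        slow = make_stratum([3000.0] * 5)
        trials = pd.concat([good, slow], ignore_index=True)
        trials["trial"] = np.arange(1, len(trials) + 1)
        cfg = TreatmentConfig(min_sessions_per_participant=1)
        clean, _ = run_treatment(trials, cfg)
        assert len(clean) == 0
        from ddmtrain.preprocessing import _apply_trimming, filter_sessions
        reversed_order = _apply_trimming(filter_sessions(trials, cfg, stage="min_trials"), cfg)
        assert len(reversed_order) > 100

    def test_not_idempotent_in_general(self):
        """Re-running trimming on trimmed data can remove more trials.

        The outlier cluster inflates the first-pass MAD enough to keep
        600 ms; once the cluster is gone, the recomputed cut drops it.
        """
        rts = [400, 420, 440, 460, 480, 600, 1400, 1400, 1400]
        once = trim_rts(make_stratum(rts))
        assert sorted(once["rt_ms"]) == [400, 420, 440, 460, 480, 600]
        twice = trim_rts(once)
        assert sorted(twice["rt_ms"]) == [400, 420, 440, 460, 480]


class TestDataTreatmentEstimator:
    def test_fit_transform_matches_run_treatment(self, tiny_study, tiny_treatment_config):
        trials, _ = tiny_study
        est = DataTreatment(tiny_treatment_config)
        out = est.fit_transform(trials)
        clean, report = run_treatment(trials, tiny_treatment_config)
        pd.testing.assert_frame_equal(out, clean)
        assert est.report_.post == report.post
        assert est.n_retained_ == len(clean)

    def test_transform_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            DataTreatment().transform(make_stratum([400]))

    def test_get_set_params_roundtrip(self):
        cfg = TreatmentConfig(mad_multiplier=3.0)
        est = DataTreatment().set_params(config=cfg)
        assert est.get_params()["config"].mad_multiplier == 3.0
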