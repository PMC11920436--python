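import numpy as np
import pandas as pd
import pytest

from clsleep import (
    build_session_schedule,
    score_trials,
    offline_change,
    tmr_index,
    rm_anova,
    generate_behavior,
)
from clsleep.behavior import SEQUENCES, SessionSchedule
from clsleep.synth import BehaviorSimParams


class TestSchedule:
    @pytest.fixture(scope="class")
    def schedule(self):
        return build_session_schedule(seed=0)

    def test_session_block_counts(self, schedule):
        sizes = schedule.blocks.groupby("session").size()
        assert sizes["pre_training"] == 63
        assert sizes["pre_test"] == 9
        assert sizes["post_training"] == 63
        assert sizes["random_pre"] == sizes["random_post"] == 4

    def test_blocks_per_sequence(self, schedule):
        b = schedule.blocks
        for sess, per in (("pre_training", 21), ("pre_test", 3),
                          ("post_training", 21)):
            counts = b[b["session"] == sess].groupby("sequence").size()
            assert (counts == per).all() and len(counts) == 3

    def test_press_counts(self, schedule):
        b = schedule.blocks
        assert (b[b["sequence"] != "random"]["n_presses"] == 20).all()
        assert (b[b["sequence"] == "random"]["n_presses"] == 60).all()

    def test_sequences_are_the_three_five_element_patterns(self):
        assert SEQUENCES == {"A": (4, 7, 2, 8, 3), "B": (1, 6, 3, 5, 2),
                             "C": (7, 3, 8, 4, 6)}

    def test_condition_and_sound_maps_are_seeded_bijections(self):
        s1 = build_session_schedule(seed=5)
        s2 = build_session_schedule(seed=5)
        assert s1.condition_map == s2.condition_map
        assert s1.sound_map == s2.sound_map
        assert sorted(s1.condition_map.values()) == ["down", "not", "up"]
        assert len(set(s1.sound_map.values())) == 3
        maps = {tuple(build_session_schedule(seed=s).condition_map.items())
                for s in range(12)}
        assert len(maps) > 1          # varies across subjects


class TestScoring:
    def _table(self, rts, correct=None):
        n = len(rts)
        return pd.DataFrame({
            "subject": 0, "session": "pre_test", "condition": "up",
            "block": 0, "press_index": np.arange(n), "key_expected": 1,
            "key_pressed": 1, "rt_ms": rts,
            "correct": correct if correct is not None else [True] * n,
        })

    def test_equal_rts_no_outliers(self):
        scores, summary = score_trials(self._table([300.0] * 20))
        assert summary["n_outliers"] == 0
        assert scores["median_rt_ms"].iloc[0] == 300.0
        assert scores["accuracy_pct"].iloc[0] == 100.0

    def test_tukey_fence_flags_extreme_rt(self):
        """19 x 300 ms plus one 3000 ms press: the outlier is discarded
        and the block median stays 300 ms."""
        scores, summary = score_trials(self._table([300.0] * 19 + [3000.0]))
        assert summary["n_outliers"] == 1
        assert scores["median_rt_ms"].iloc[0] == 300.0
        assert scores["n_analyzed"].iloc[0] == 19

    def test_incorrect_trials_never_outliers(self):
        rts = [300.0] * 19 + [3000.0]
        correct = [True] * 19 + [False]
        _, summary = score_trials(self._table(rts, correct))
        assert summary["n_outliers"] == 0

    def test_all_incorrect_block_raises(self):
        with pytest.raises(ValueError):
            score_trials(self._table([300.0] * 20, [False] * 20))

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError):
            score_trials(self._table([300.0] * 19 + [0.0]))


class TestOfflineChange:
    def _scores(self, pre, post):
        rows = []
        for cond in ("up", "down", "not"):
            for b in range(3):
                rows.append({"subject": 0, "session": "pre_test",
                             "condition": cond, "block": b,
                             "median_rt_ms": pre[cond]})
            for b in range(5):
                rows.append({"subject": 0, "session": "post_training",
                             "condition": cond, "block": b,
                             "median_rt_ms": post[cond]})
        return pd.DataFrame(rows)

    def test_ten_percent_speedup(self):
        ch = offline_change(self._scores(
            {"up": 500.0, "down": 500.0, "not": 500.0},
            {"up": 450.0, "down": 500.0, "not": 525.0}))
        assert ch.loc[0, "up"] == pytest.approx(10.0)
        assert ch.loc[0, "down"] == pytest.approx(0.0)
        assert ch.loc[0, "not"] == pytest.approx(-5.0)

    def test_scale_invariance(self):
        s = self._scores({"up": 480.0, "down": 510.0, "not": 495.0},
                         {"up": 430.0, "down": 505.0, "not": 470.0})
        c1 = offline_change(s)
        s2 = s.copy()
        s2["median_rt_ms"] *= 3.7
        c2 = offline_change(s2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_missing_blocks_rejected(self):
        s = self._scores({"up": 500.0, "down": 500.0, "not": 500.0},
                         {"up": 450.0, "down": 500.0, "not": 525.0})
        with pytest.raises(ValueError):
            offline_change(s[~((s["session"] == "pre_test")
                               & (s["condition"] == "up")
                               & (s["block"] == 2))])

    def test_tmr_index_definition(self):
        ch = pd.DataFrame({"up": [8.0], "down": [2.0], "not": [7.0]})
        idx = tmr_index(ch)
        assert idx.loc[0, "tmr_index_up"] == pytest.approx(1.0)
        assert idx.loc[0, "tmr_index_down"] == pytest.approx(-5.0)


class TestRmAnova:
    def test_identical_columns_give_f_zero_p_one(self):
        y = np.tile(np.array([3.0, 5.0, 4.0, 6.0])[:, None], (1, 3))
        res = rm_anova(y, posthoc=False)
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_hand_computed_sums_of_squares(self):
        """Textbook 4-subject, 3-condition table checked against an
        explicit sums-of-squares calculation."""
        y = np.array([[10.0, 8.0, 6.0],
                      [9.0, 7.0, 5.0],
                      [11.0, 9.0, 8.0],
                      [10.0, 8.0, 7.0]])
        # independent oracle: direct arithmetic
        gm = y.mean()
        ss_cond = 4 * sum((y[:, j].mean() - gm) ** 2 for j in range(3))
        ss_subj = 3 * sum((y[i].mean() - gm) ** 2 for i in range(4))
        ss_tot = ((y - gm) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        f_hand = (ss_cond / 2) / (ss_err / 6)
        res = rm_anova(y)
        assert res["F"] == pytest.approx(f_hand, abs=1e-10)
        assert res["eta2_p"] == pytest.approx(
            ss_cond / (ss_cond + ss_err), abs=1e-10)
        assert res["df1"] == 2 and res["df2"] == 6

    def test_matches_pingouin_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.standard_normal((12, 3)) + np.array([0.0, 0.4, 0.1])
        res = rm_anova(y, posthoc=False)
        df = (pd.DataFrame(y, columns=list("abc")).reset_index()
              .melt(id_vars="index"))
        ref = pg.rm_anova(data=df, dv="value", within="variable",
                          subject="index", correction=True, effsize="np2")
        assert res["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res["p"] == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)
        assert res["gg_epsilon"] == pytest.approx(float(ref["eps"].iloc[0]),
                                                  rel=1e-6)
        assert res["p_gg"] == pytest.approx(float(ref["p_GG_corr"].iloc[0]),
                                            rel=1e-6)
        assert res["eta2_p"] == pytest.approx(float(ref["np2"].iloc[0]),
                                              rel=1e-9)

    def test_posthoc_fdr_and_d(self, rng):
        y = rng.standard_normal((15, 3))
        y[:, 0] += 1.0
        res = rm_anova(y)
        ph = res["posthoc"]
        assert len(ph) == 3
        assert (ph["p_fdr"] >= ph["p"] - 1e-15).all()
        assert ph["df"].eq(14).all()

    def test_null_calibration(self, rng):
        hits = 0
        reps = 600
        for _ in range(reps):
            y = rng.standard_normal((28, 3)) + rng.standard_normal(28)[:, None]
            hits += rm_anova(y, posthoc=False)["p"] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.025)

    def test_incomplete_cases_rejected(self):
        y = np.ones((4, 3))
        y[1, 2] = np.nan
        with pytest.raises(ValueError):
            rm_anova(y)


class TestEndToEndRecovery:
    def test_planted_ordering_recovered_with_posthocs(self):
        """28 synthetic subjects with gains up ~ not > down: the pipeline
        finds the ordering with an FDR-significant down deficit."""
        sch = build_session_schedule(seed=1)
        hits = 0
        for rep in range(10):
            tab = generate_behavior(sch, BehaviorSimParams(seed=100 + rep))
            scores, _ = score_trials(tab)
            ch = offline_change(scores)
            res = rm_anova(ch[["up", "down", "not"]])
            ph = res["posthoc"].set_index(["a", "b"])
            down_vs_up = ph.loc[("up", "down"), "p_fdr"]
            down_vs_not = ph.loc[("down", "not"), "p_fdr"]
            ok = (ch["up"].mean() > ch["down"].mean()
                  and ch["not"].mean() > ch["down"].mean()
                  and down_vs_up < 0.05 and down_vs_not < 0.05)
            hits += ok
        assert hits >= 8
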