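"""Serial reaction time task: schedules, scoring and consolidation stats.

The task uses three 5-element bimanual sequences (A: 4-7-2-8-3,
B: 1-6-3-5-2, C: 7-3-8-4-6; keys 1-8, left to right little finger),
pseudo-randomly mapped to the up-/down-/not-reactivated conditions per
subject. A night of sleep separates the pre-night session (63 training
blocks, 21 per sequence, then a 9-block test) from the post-night
session (63 blocks). Sequential blocks are 4 repetitions x 5 elements =
20 presses; pseudo-random blocks are 12 patterns x 5 keys = 60 presses.

Performance per block is the median response time (RT) of correct,
non-outlier presses; outliers among correct trials are flagged by Tukey
fences (1.5 x IQR) per subject x session x condition. The offline change
in performance speed is

    100 * (mean(pre-test RT) - mean(first-3-post RT)) / mean(pre-test RT)

so a positive value means faster (better) after sleep, and the TMR index
is the offline change of a reactivated condition minus the
not-reactivated one. The group statistic is a one-way repeated-measures
ANOVA with Greenhouse-Geisser correction, partial eta squared, and
FDR-corrected pairwise paired t posthocs with Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SEQUENCES = {"A": (4, 7, 2, 8, 3), "B": (1, 6, 3, 5, 2), "C": (7, 3, 8, 4, 6)}
CONDITIONS = ("up", "down", "not")
SEQ_PRESSES = 20            # 4 repetitions x 5 elements
RANDOM_PRESSES = 60         # 12 patterns x 5 keys
REST_S = 10.0

SESSION_BLOCKS = {
    "pre_training": 21,     # per sequence
    "pre_test": 3,
    "post_training": 21,
}
RANDOM_BLOCKS = 4           # per random session


@dataclass
class SessionSchedule:
    """Block-level schedule plus the seeded sequence/condition mapping."""

    blocks: pd.DataFrame            # session, block, sequence, condition, n_presses
    condition_map: dict             # sequence -> condition
    sound_map: dict                 # condition -> sound name
    sequences: dict = field(default_factory=lambda: dict(SEQUENCES))
    rest_s: float = REST_S
    seed: int = 0


def build_session_schedule(seed=0):
    """Build the full experiment schedule for one subject.

    The sequence -> condition and condition -> sound assignments are a
    seeded bijection (fixed within subject, pseudo-randomized across
    subjects via the seed); within each session the sequence order is a
    seeded pseudo-random interleaving with the per-sequence block counts
    fixed (21/21/21 training, 3/3/3 test, 21/21/21 post-training).
    """
    rng = np.random.default_rng(seed)
    seqs = list(SEQUENCES)
    conds = list(CONDITIONS)
    sounds = ["low_tone", "noise", "high_tone"]
    rng.shuffle(conds)
    condition_map = dict(zip(seqs, conds))
    rng.shuffle(sounds)
    sound_map = dict(zip(CONDITIONS, sounds))

    rows = []

    def add_session(name, per_seq):
        order = np.repeat(seqs, per_seq)
        rng.shuffle(order)
        for b, sq in enumerate(order):
            rows.append({"session": name, "block": b, "sequence": sq,
                         "condition": condition_map[sq],
                         "n_presses": SEQ_PRESSES})

    def add_random(name):
        for b in range(RANDOM_BLOCKS):
            rows.append({"session": name, "block": b, "sequence": "random",
                         "condition": "random", "n_presses": RANDOM_PRESSES})

    add_random("random_pre")
    add_session("pre_training", SESSION_BLOCKS["pre_training"])
    add_session("pre_test", SESSION_BLOCKS["pre_test"])
    add_session("post_training", SESSION_BLOCKS["post_training"])
    add_random("random_post")
    return SessionSchedule(pd.DataFrame(rows), condition_map, sound_map,
                           seed=seed)


def score_trials(trials: pd.DataFrame):
    """Per-block median RT (correct, non-outlier) and accuracy.

    Outliers among *correct* trials are flagged with Tukey fences
    (Q1 - 1.5 IQR, Q3 + 1.5 IQR) computed per subject x session x
    condition. Returns ``(block_scores, summary)`` where ``block_scores``
    has one row per subject x session x condition x block with
    ``median_rt_ms`` and ``accuracy_pct``, and ``summary`` reports the
    percentage of discarded trials (incorrect + outlier).
    """
    df = trials.copy()
    if (df["rt_ms"] <= 0).any():
        raise ValueError("RTs must be positive")
    correct = df["correct"].astype(bool)
    grp_cols = ["subject", "session", "condition"]
    corr = df[correct]
    q = corr.groupby(grp_cols)["rt_ms"]
    q1 = q.transform(lambda s: s.quantile(0.25))
    q3 = q.transform(lambda s: s.quantile(0.75))
    iqr = q3 - q1
    out_mask = (corr["rt_ms"] < q1 - 1.5 * iqr) | (corr["rt_ms"] > q3 + 1.5 * iqr)
    df["outlier"] = False
    df.loc[out_mask.index[out_mask], "outlier"] = True

    keep = correct & ~df["outlier"]
    block_cols = grp_cols + ["block"]
    g_all = df.groupby(block_cols, sort=True)
    acc = 100.0 * g_all["correct"].mean()
    surv = df[keep].groupby(block_cols, sort=True)["rt_ms"]
    block_scores = pd.DataFrame({
        "accuracy_pct": acc,
        "median_rt_ms": surv.median(),
        "n_analyzed": surv.size(),
    }).reset_index()
    empty = block_scores["n_analyzed"].isna() | (block_scores["n_analyzed"] == 0)
    if empty.any():
        bad = block_scores[empty].iloc[0]
        raise ValueError(
            f"block with zero surviving trials: {tuple(bad[block_cols])}")
    discarded_pct = 100.0 * (1.0 - keep.mean())
    summary = {"discarded_pct": float(discarded_pct),
               "n_trials": int(len(df)),
               "n_outliers": int(df["outlier"].sum())}
    return block_scores, summary


def offline_change(block_scores: pd.DataFrame, n_blocks=3):
    """Per subject x condition offline change in performance speed (%).

    Uses the mean of the ``n_blocks`` pre-test block medians and the
    mean of the first ``n_blocks`` post-training block medians:
    ``100 * (pre - post) / pre`` (RT decrease -> positive change).
    Scale-invariant: multiplying all RTs by c > 0 leaves it unchanged.
    """
    out = []
    for (subj, cond), g in block_scores[
            block_scores["condition"].isin(CONDITIONS)].groupby(
            ["subject", "condition"]):
        pre = g[g["session"] == "pre_test"].sort_values("block")
        post = g[g["session"] == "post_training"].sort_values("block")
        if len(pre) < n_blocks or len(post) < n_blocks:
            raise ValueError(
                f"missing blocks for subject {subj}, condition {cond}")
        pre_rt = pre["median_rt_ms"].iloc[:n_blocks].mean()
        post_rt = post["median_rt_ms"].iloc[:n_blocks].mean()
        out.append({"subject": subj, "condition": cond,
                    "offline_change_pct": 100.0 * (pre_rt - post_rt) / pre_rt})
    return (pd.DataFrame(out)
            .pivot(index="subject", columns="condition",
                   values="offline_change_pct"))


def tmr_index(changes: pd.DataFrame):
    """TMR indices: reactivated minus not-reactivated offline change."""
    return pd.DataFrame({
        "tmr_index_up": changes["up"] - changes["not"],
        "tmr_index_down": changes["down"] - changes["not"],
    })


def _gg_epsilon(y):
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = y.shape[1]
    s = np.cov(y, rowvar=False)
    dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) \
        + s.mean()
    tr = np.trace(dc)
    denom = (k - 1) * np.sum(dc * dc)
    if denom <= 0:
        return 1.0
    return float(min(max(tr * tr / denom, 1.0 / (k - 1)), 1.0))


def rm_anova(values, posthoc=True):
    """One-way repeated-measures ANOVA with GG correction and posthocs.

    ``values`` is a subjects x conditions array or wide DataFrame
    (complete cases). Returns a dict with F, df, p, the
    Greenhouse-Geisser epsilon and corrected p, partial eta squared, and
    (optionally) a posthoc DataFrame of all pairwise paired t tests with
    Benjamini-Hochberg FDR-adjusted p-values and Cohen's d.
    """
    if isinstance(values, pd.DataFrame):
        names = list(values.columns)
        y = values.to_numpy(dtype=float)
    else:
        y = np.asarray(values, dtype=float)
        names = [f"c{i}" for i in range(y.shape[1])]
    if y.ndim != 2:
        raise ValueError("values must be 2-D (subjects x conditions)")
    if np.isnan(y).any():
        raise ValueError("missing cells; repeated-measures ANOVA needs "
                         "complete cases")
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    gm = y.mean()
    ss_subj = k * np.sum((y.mean(axis=1) - gm) ** 2)
    ss_cond = n * np.sum((y.mean(axis=0) - gm) ** 2)
    ss_tot = np.sum((y - gm) ** 2)
    ss_err = ss_tot - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ss_cond <= 0 or ms_err <= 0:
        f_val, p = 0.0, 1.0
        eps = 1.0
        p_gg = 1.0
        eta2 = 0.0
    else:
        f_val = ms_cond / ms_err
        p = float(stats.f.sf(f_val, df1, df2))
        eps = _gg_epsilon(y)
        p_gg = float(stats.f.sf(f_val, df1 * eps, df2 * eps))
        eta2 = ss_cond / (ss_cond + ss_err)
    result = {
        "F": float(f_val), "df1": df1, "df2": df2, "p": float(p),
        "gg_epsilon": float(eps), "p_gg": float(p_gg),
        "eta2_p": float(eta2),
        "ss_cond": float(ss_cond), "ss_err": float(ss_err),
        "ss_subj": float(ss_subj),
    }
    if posthoc:
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                d = y[:, i] - y[:, j]
                sd = d.std(ddof=1)
                tt, pp = stats.ttest_rel(y[:, i], y[:, j])
                rows.append({
                    "a": names[i], "b": names[j], "t": float(tt),
                    "df": n - 1, "p": float(pp),
                    "cohens_d": float(d.mean() / sd) if sd > 0 else np.nan,
                })
        ph = pd.DataFrame(rows)
        if len(ph):
            ph["p_fdr"] = multipletests(ph["p"], method="fdr_bh")[1]
        result["posthoc"] = ph
    return result
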