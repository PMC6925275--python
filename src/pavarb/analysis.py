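"""Behavioral analyses: exclusions, Go bias, weight-quantile and timecourse
analyses, the bias-variance decomposition of choice behavior, and group
statistics.

Accuracy is always computed over trials whose optimal action is defined;
the Low Control decoy (equal reward rates for both actions) has no optimal
action and is excluded from accuracy and from the choice-bias sum. The
choice variance is computed over all trials by default (configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pavarb.task import trials_to_frame

GO = "go"
NOGO = "nogo"
UNDEFINED = "undefined"


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(list(trials))


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    conditions: tuple[str, ...]
    n_trials: int
    accuracy_overall: float
    accuracy_by_stimulus: dict[str, float]
    go_bias: float
    bias: float
    variance: float
    #: variance restricted to the stimuli shared by both conditions
    #: (go_win, nogo_win); the right scope for condition contrasts.
    variance_shared: float = math.nan
    excluded: bool = False
    exclusion_reason: str = ""


def go_bias(trials) -> float:
    """Accuracy on Go-to-Win trials minus accuracy on No-Go-to-Win trials.

    Equals fraction Go on go_win minus fraction No-Go on nogo_win; 0 under
    purely instrumental control, positive under Pavlovian influence.
    """
    df = _as_frame(trials)
    gw = df[df["stimulus"] == "go_win"]
    ngw = df[df["stimulus"] == "nogo_win"]
    if gw.empty or ngw.empty:
        raise ValueError("go_bias requires both go_win and nogo_win trials")
    acc_gw = float((gw["action"] == GO).mean())
    acc_ngw = float((ngw["action"] == NOGO).mean())
    return acc_gw - acc_ngw


def bias_variance(trials, variance_scope: str = "all") -> tuple[float, float]:
    """Decompose choice behavior into bias and variance.

    bias: mean over trials with a defined optimal action of
    I[chose Go] - I[optimal is Go]. variance: mean squared deviation of
    I[chose Go] from the participant's own mean Go rate, which equals
    p*(1-p) for Go rate p.

    ``variance_scope`` selects which trials enter the variance:
    ``"all"`` (default, the literal definition), ``"defined"`` (only trials
    with a defined optimal action), or ``"shared"`` (only the go_win and
    nogo_win stimuli, which are identical across conditions — the scope to
    use when contrasting conditions, since the decoy's schedule itself
    differs between them).
    """
    df = _as_frame(trials)
    defined = df[df["optimal_action"] != UNDEFINED]
    if defined.empty:
        raise ValueError("no trials with a defined optimal action")
    go_t = (defined["action"] == GO).to_numpy(dtype=float)
    go_opt = (defined["optimal_action"] == GO).to_numpy(dtype=float)
    bias = float(np.mean(go_t - go_opt))

    if variance_scope == "all":
        var_df = df
    elif variance_scope == "defined":
        var_df = defined
    elif variance_scope == "shared":
        var_df = df[df["stimulus"].isin(["go_win", "nogo_win"])]
    else:
        raise ValueError(f"unknown variance_scope {variance_scope!r}")
    go_all = (var_df["action"] == GO).to_numpy(dtype=float)
    variance = float(np.mean((go_all - go_all.mean()) ** 2))
    return bias, variance


def summarize_participant(trials) -> ParticipantSummary:
    """Per-participant accuracy, Go bias, and bias-variance values."""
    df = _as_frame(trials)
    pids = df["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected one participant, got {list(pids)}")
    defined = df[df["optimal_action"] != UNDEFINED]
    if defined.empty:
        raise ValueError("participant has no trials with defined optimal action")
    correct = defined["action"] == defined["optimal_action"]
    acc_by_stim = {
        stim: float((sub["action"] == sub["optimal_action"]).mean())
        for stim, sub in defined.groupby("stimulus", observed=True)
    }
    bias, variance = bias_variance(df)
    _, variance_shared = bias_variance(df, variance_scope="shared")
    return ParticipantSummary(
        participant_id=str(pids[0]),
        conditions=tuple(sorted(df["condition"].unique())),
        n_trials=len(df),
        accuracy_overall=float(correct.mean()),
        accuracy_by_stimulus=acc_by_stim,
        go_bias=go_bias(df),
        bias=bias,
        variance=variance,
        variance_shared=variance_shared,
    )


def apply_exclusions(
    summaries: Sequence[ParticipantSummary],
) -> tuple[list[ParticipantSummary], list[ParticipantSummary]]:
    """Flag participants who were incorrect on >=50% of trials overall, or
    below 30% accuracy on any single stimulus. Idempotent."""
    kept: list[ParticipantSummary] = []
    excluded: list[ParticipantSummary] = []
    for s in summaries:
        reasons = []
        if 1.0 - s.accuracy_overall >= 0.5:
            reasons.append(f"incorrect on {1.0 - s.accuracy_overall:.0%} of trials")
        low = {k: v for k, v in s.accuracy_by_stimulus.items() if v < 0.30}
        for stim, acc in sorted(low.items()):
            reasons.append(f"accuracy {acc:.0%} on {stim}")
        if reasons:
            excluded.append(
                ParticipantSummary(
                    **{
                        **s.__dict__,
                        "excluded": True,
                        "exclusion_reason": "; ".join(reasons),
                    }
                )
            )
        else:
            kept.append(s)
    return kept, excluded


def summarize_cohort(trials, split_by_condition: bool = False) -> list[ParticipantSummary]:
    """Summaries for every participant; optionally one summary per
    (participant, condition) half — used for within-participant designs."""
    df = _as_frame(trials)
    out: list[ParticipantSummary] = []
    keys = ["participant_id", "condition"] if split_by_condition else ["participant_id"]
    for _, sub in df.groupby(keys, observed=True):
        out.append(summarize_participant(sub))
    return out


def go_bias_by_weight_quantile(
    trials, weights: pd.DataFrame, n_quantiles: int = 5
) -> pd.DataFrame:
    """Go bias as a function of within-participant weight quantile.

    ``weights`` carries columns participant_id, trial, w aligned to the
    trials. Each participant's trials are ranked by their own w (stable
    ranking spreads ties evenly across bins) and split into ``n_quantiles``
    equal-count bins; the Go bias is computed per bin and averaged across
    participants. Returns a frame with quantile, mean go_bias, sem, and n.
    """
    df = _as_frame(trials).merge(weights, on=["participant_id", "trial"], validate="1:1")
    per_bin: dict[int, list[float]] = {q: [] for q in range(n_quantiles)}
    for pid, sub in df.groupby("participant_id"):
        if len(sub) < n_quantiles:
            raise ValueError(f"participant {pid}: fewer trials than quantiles")
        sub = sub.sort_values("trial")
        order = np.argsort(sub["w"].to_numpy(), kind="stable")
        ranks = np.empty(len(sub), dtype=int)
        ranks[order] = np.arange(len(sub))
        bins = (ranks * n_quantiles) // len(sub)
        for q in range(n_quantiles):
            bin_trials = sub.iloc[bins == q]
            try:
                per_bin[q].append(go_bias(bin_trials))
            except ValueError:
                continue  # bin lacks one stimulus type for this participant
    rows = []
    for q in range(n_quantiles):
        vals = np.array(per_bin[q], dtype=float)
        rows.append(
            {
                "quantile": q,
                "go_bias": float(vals.mean()) if vals.size else math.nan,
                "sem": float(stats.sem(vals)) if vals.size > 1 else math.nan,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TimecourseResult:
    """Go-bias timecourse over within-stimulus presentation index."""

    index: np.ndarray  # presentation index k = 1..n
    mean: np.ndarray  # cohort mean go-bias at each k
    sem: np.ndarray
    smoothed: np.ndarray  # moving-average of the mean series
    slopes: np.ndarray  # per-participant OLS slope of go_bias_k on log k
    t_stat: float
    p_value: float


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    kernel = np.ones(window) / window
    # centered, edge-shortened average
    padded = np.convolve(y, kernel, mode="same")
    norm = np.convolve(np.ones_like(y), kernel, mode="same")
    return padded / norm


def go_bias_timecourse(trials, window: int = 5) -> TimecourseResult:
    """Per-presentation-index Go bias and its decline over (log) trials.

    For presentation index k, a participant's trial-level Go bias is
    I[Go on the k-th go_win trial] - I[No-Go on the k-th nogo_win trial];
    sessions with multiple blocks average across blocks. The per-participant
    OLS slope of this series on log(k) is returned along with a one-sample
    t-test of the slopes against zero.
    """
    df = _as_frame(trials)
    per_participant: list[np.ndarray] = []
    n_index: int | None = None
    for pid, sub in df.groupby("participant_id"):
        block_series = []
        for _, blk in sub.groupby("block"):
            gw = blk[blk["stimulus"] == "go_win"].sort_values("trial")
            ngw = blk[blk["stimulus"] == "nogo_win"].sort_values("trial")
            if len(gw) != len(ngw):
                raise ValueError(
                    f"participant {pid}: unequal go_win/nogo_win counts in a block"
                )
            series = (gw["action"] == GO).to_numpy(float) - (
                ngw["action"] == NOGO
            ).to_numpy(float)
            block_series.append(series)
        lengths = {len(s) for s in block_series}
        if len(lengths) != 1:
            raise ValueError(f"participant {pid}: unequal stimulus counts across blocks")
        series = np.mean(block_series, axis=0)
        if n_index is None:
            n_index = len(series)
        elif n_index != len(series):
            raise ValueError("participants have unequal within-stimulus trial counts")
        per_participant.append(series)

    mat = np.array(per_participant)
    assert n_index is not None
    k = np.arange(1, n_index + 1)
    logk = np.log(k)
    x = logk - logk.mean()
    denom = float((x**2).sum())
    slopes = (mat - mat.mean(axis=1, keepdims=True)) @ x / denom
    mean = mat.mean(axis=0)
    sem = stats.sem(mat, axis=0) if mat.shape[0] > 1 else np.full(n_index, math.nan)
    if mat.shape[0] > 1:
        t_stat, p_value = stats.ttest_1samp(slopes, 0.0)
    else:
        t_stat, p_value = math.nan, math.nan
    return TimecourseResult(
        index=k,
        mean=mean,
        sem=np.asarray(sem),
        smoothed=_moving_average(mean, window),
        slopes=slopes,
        t_stat=float(t_stat),
        p_value=float(p_value),
    )


def _cohens_d_two_sample(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _cohens_d_paired(diff: np.ndarray) -> float:
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(diff.mean() / sd)


def group_stats(
    lc: Sequence[ParticipantSummary],
    hc: Sequence[ParticipantSummary],
    paired: bool = False,
) -> dict:
    """Condition contrasts on go_bias, bias and variance.

    Two-sample Welch t-tests for between-participant designs; paired t-tests
    (summaries aligned by participant id) for within-participant designs.
    Cohen's d uses the pooled SD (two-sample) or the SD of differences
    (paired).
    """
    if len(lc) < 2 or len(hc) < 2:
        raise ValueError("each group needs at least two participants")
    if paired:
        lc = sorted(lc, key=lambda s: s.participant_id)
        hc = sorted(hc, key=lambda s: s.participant_id)
        if [s.participant_id for s in lc] != [s.participant_id for s in hc]:
            raise ValueError("paired groups must contain the same participants")
    report: dict = {"design": "paired" if paired else "between", "n_lc": len(lc), "n_hc": len(hc)}
    for metric in ("go_bias", "bias", "variance", "variance_shared"):
        a = np.array([getattr(s, metric) for s in lc], dtype=float)
        b = np.array([getattr(s, metric) for s in hc], dtype=float)
        if paired:
            t, p = stats.ttest_rel(a, b)
            d = _cohens_d_paired(a - b)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            d = _cohens_d_two_sample(a, b)
        report[metric] = {
            "mean_lc": float(a.mean()),
            "mean_hc": float(b.mean()),
            "t": float(t),
            "p": float(p),
            "d": d,
        }
    return report


def weight_correlation(mean_adaptive_w: Sequence[float], fitted_w: Sequence[float]) -> dict:
    """Pearson correlation between per-participant mean adaptive weight and
    the fitted fixed weight."""
    a = np.asarray(mean_adaptive_w, dtype=float)
    b = np.asarray(fitted_w, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need aligned vectors with at least 3 participants")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p), "n": int(a.size)}


def summaries_to_frame(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id,
            "conditions": "+".join(s.conditions),
            "n_trials": s.n_trials,
            "accuracy_overall": s.accuracy_overall,
            "go_bias": s.go_bias,
            "bias": s.bias,
            "variance": s.variance,
            "variance_shared": s.variance_shared,
            "excluded": s.excluded,
            "exclusion_reason": s.exclusion_reason,
        }
        for stim, acc in s.accuracy_by_stimulus.items():
            row[f"accuracy_{stim}"] = acc
        rows.append(row)
    return pd.DataFrame(rows)
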