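"""Per-subject behavioral measures for the stop-signal task.

Implements the analysis chain applied to each subject's trial log:

* IQR-based outlier rejection of go RTs within each stop-signal probability
  level (values beyond 1.5 x IQR from the 25th/75th percentiles);
* proactive inhibition as the OLS slope of mean go RT on nominal stop-signal
  probability (ms per unit probability);
* reactive inhibition as SSRT by the integration method: the nth fastest go
  RT (n = p[respond|signal] x number of go RTs, misses included at the
  1250 ms deadline) minus the mean SSD, per stimulus type, pooled across the
  yellow/orange/red contexts;
* race-model validity diagnostics (p[respond|signal] near 0.50, failed-stop
  RT faster than go RT) and the >70% respond-on-stop exclusion rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONTEXT_PROBABILITY, STIMULUS_TYPES

RESPONDED_GO = ("go_correct", "go_error")

#: p[respond|signal] band treated as consistent with successful tracking
P_RESPOND_VALID_RANGE = (0.35, 0.65)
#: exclusion threshold: more than 70% go responses on stop trials
P_RESPOND_EXCLUSION = 0.70


def filter_rt_outliers(rts, min_n: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """IQR outlier rejection for one (subject, probability-level) RT cell.

    Returns (kept values, outlier mask over the input). Quantiles use linear
    interpolation between order statistics. Cells with fewer than ``min_n``
    RTs are returned unfiltered.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < min_n:
        return rts, np.zeros(rts.size, dtype=bool)
    q25, q75 = np.percentile(rts, [25, 75], method="linear")
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    mask = (rts < lo) | (rts > hi)
    return rts[~mask], mask


def proactive_slope(context_means, probabilities=None) -> float:
    """OLS slope of mean go RT on nominal stop-signal probability.

    ``context_means`` are the four context mean RTs ordered green -> red;
    the slope is in ms per unit probability (the proactive-inhibition
    measure: how much responding slows as stop likelihood rises).
    """
    y = np.asarray(context_means, dtype=float)
    if probabilities is None:
        probabilities = [CONTEXT_PROBABILITY[c] for c in ("green", "yellow", "orange", "red")]
    x = np.asarray(probabilities, dtype=float)
    if y.shape != x.shape:
        raise ValueError("context_means and probabilities must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite context mean RT")
    xc = x - x.mean()
    return float(xc @ y / (xc @ xc))


def estimate_ssrt_integration(go_rts_with_misses, p_respond: float, mean_ssd: float) -> float:
    """Integration-method SSRT.

    ``go_rts_with_misses`` is the full go-RT distribution with omissions
    already substituted by the 1250 ms deadline. The estimate is the RT at
    1-based rank ceil(p_respond * N) of the sorted distribution (capped at
    N) minus the mean SSD.
    """
    rts = np.sort(np.asarray(go_rts_with_misses, dtype=float))
    n = rts.size
    if n == 0:
        raise ValueError("empty go RT distribution")
    if not 0.0 < p_respond <= 1.0:
        raise ValueError("p_respond must lie in (0, 1]")
    rank = min(math.ceil(p_respond * n), n)
    return float(rts[rank - 1] - mean_ssd)


def exclusion_check(p_respond: float) -> bool:
    """True iff the subject responded on strictly more than 70% of stop trials."""
    if not 0.0 <= p_respond <= 1.0:
        raise ValueError("p_respond must lie in [0, 1]")
    return p_respond > P_RESPOND_EXCLUSION


@dataclass(frozen=True)
class ValidityDiagnostics:
    """Race-model validity checks for one subject (stop contexts pooled)."""

    p_respond_pooled: float
    p_respond_by_stimulus: dict
    mean_failed_stop_rt: float
    mean_go_rt: float
    tracking_ok: bool
    independence_ok: bool | None  # None when not evaluable (no failed stops)


def validity_checks(records: pd.DataFrame) -> ValidityDiagnostics:
    """Diagnostics of adaptive tracking and race-model independence.

    Tracking passes when pooled p[respond|signal] lies in [0.35, 0.65];
    independence passes when mean failed-stop RT < mean go RT (both pooled
    across the stop-signal contexts). With no failed stops the independence
    check is reported as not evaluable.
    """
    stops = records[records["trial_kind"] == "stop"]
    if len(stops) == 0:
        raise ValueError("validity checks need at least one stop trial")
    p_pooled = float((stops["outcome"] == "stop_respond").mean())
    p_by_stim = {
        st: float((sub["outcome"] == "stop_respond").mean()) if len(sub) else float("nan")
        for st, sub in stops.groupby("stimulus_type")
    }
    stop_ctx = stops["context"].unique()
    go_resp = records[
        (records["trial_kind"] == "go")
        & records["context"].isin(stop_ctx)
        & records["outcome"].isin(RESPONDED_GO)
    ]
    failed = stops[stops["outcome"] == "stop_respond"]
    mean_go = float(go_resp["rt_ms"].mean()) if len(go_resp) else float("nan")
    mean_failed = float(failed["rt_ms"].mean()) if len(failed) else float("nan")
    independence = None
    if len(failed) and len(go_resp):
        independence = bool(mean_failed < mean_go)
    return ValidityDiagnostics(
        p_respond_pooled=p_pooled,
        p_respond_by_stimulus=p_by_stim,
        mean_failed_stop_rt=mean_failed,
        mean_go_rt=mean_go,
        tracking_ok=P_RESPOND_VALID_RANGE[0] <= p_pooled <= P_RESPOND_VALID_RANGE[1],
        independence_ok=independence,
    )


@dataclass
class SubjectSummary:
    """Derived behavioral measures for one subject."""

    subject_id: str
    group: str
    go_rt_mean: dict  # (context, stimulus_type) -> ms, outlier-filtered
    go_rt_mean_context: dict  # context -> ms, pooled over stimulus types
    proactive_slope_by_stimulus: dict  # stimulus_type -> ms/unit probability
    proactive_slope_pooled: float
    ssrt: dict  # stimulus_type -> ms (None when no stop trials)
    mean_ssd: dict  # stimulus_type -> ms
    p_respond_signal: dict  # stimulus_type -> probability
    p_respond_pooled: float | None
    mean_failed_stop_rt: float | None
    mean_go_rt: float | None
    p_miss: dict  # context -> probability of go omission
    accuracy: dict  # context -> proportion correct among responded go trials
    excluded: bool
    exclusion_reason: str | None

    def to_row(self) -> dict:
        """Flatten to one row for the subject-summary table."""
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "proactive_slope_pooled": self.proactive_slope_pooled,
            "p_respond_pooled": self.p_respond_pooled,
            "mean_failed_stop_rt": self.mean_failed_stop_rt,
            "mean_go_rt": self.mean_go_rt,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason or "",
        }
        for (ctx, stim), v in self.go_rt_mean.items():
            row[f"go_rt_{ctx}_{stim}"] = v
        for ctx, v in self.go_rt_mean_context.items():
            row[f"go_rt_{ctx}"] = v
        for stim in STIMULUS_TYPES:
            row[f"proactive_slope_{stim}"] = self.proactive_slope_by_stimulus.get(stim)
            row[f"ssrt_{stim}"] = self.ssrt.get(stim)
            row[f"mean_ssd_{stim}"] = self.mean_ssd.get(stim)
            row[f"p_respond_{stim}"] = self.p_respond_signal.get(stim)
        for ctx, v in self.p_miss.items():
            row[f"p_miss_{ctx}"] = v
        for ctx, v in self.accuracy.items():
            row[f"accuracy_{ctx}"] = v
        return row


def _context_probabilities(records: pd.DataFrame) -> dict:
    ctxs = list(records["context"].unique())
    unknown = [c for c in ctxs if c not in CONTEXT_PROBABILITY]
    if unknown:
        raise ValueError(f"unknown context labels: {unknown}")
    return {c: CONTEXT_PROBABILITY[c] for c in ctxs}


def summarize_subject(
    records: pd.DataFrame, deadline_ms: float = 1250.0, require_full_design: bool = True
) -> SubjectSummary:
    """Compute all derived measures for one subject's trial log.

    The IQR outlier filter is applied per (context, stimulus) cell before the
    context RT means and the proactive slope. The SSRT go-RT distribution is
    deliberately unfiltered: it pools each stimulus type's go trials from the
    stop-signal contexts (yellow/orange/red), substituting omissions with the
    response deadline, and subtracts that stimulus type's mean SSD at rank
    ceil(p_respond * N). Green contributes no SSD and so stays out of the
    SSRT distribution.
    """
    probs = _context_probabilities(records)
    if require_full_design:
        missing = [c for c in CONTEXT_PROBABILITY if c not in probs]
        if missing:
            raise ValueError(f"trial log is missing contexts: {missing}")
    sid = str(records["subject_id"].iloc[0]) if "subject_id" in records else ""
    grp = str(records["group"].iloc[0]) if "group" in records else ""

    go = records[records["trial_kind"] == "go"]
    responded = go[go["outcome"].isin(RESPONDED_GO)]

    # outlier-filtered cell means -> context means -> proactive slopes
    cell_means: dict = {}
    filtered_by_context: dict = {c: [] for c in probs}
    for (ctx, stim), cell in responded.groupby(["context", "stimulus_type"]):
        kept, _ = filter_rt_outliers(cell["rt_ms"].to_numpy(float))
        cell_means[(ctx, stim)] = float(np.mean(kept)) if kept.size else float("nan")
        filtered_by_context[ctx].append(kept)
    ctx_means = {
        c: float(np.mean(np.concatenate(v))) if v and sum(len(a) for a in v) else float("nan")
        for c, v in filtered_by_context.items()
    }

    ordered = sorted(probs, key=probs.get)
    # a slope needs >= 2 distinct probability levels
    can_slope = len(set(probs.values())) >= 2
    slope_pooled = (
        proactive_slope([ctx_means[c] for c in ordered], [probs[c] for c in ordered])
        if can_slope else float("nan")
    )
    slope_by_stim = {}
    for stim in STIMULUS_TYPES:
        means = [cell_means.get((c, stim), float("nan")) for c in ordered]
        if can_slope and np.all(np.isfinite(means)):
            slope_by_stim[stim] = proactive_slope(means, [probs[c] for c in ordered])
        else:
            slope_by_stim[stim] = float("nan")

    # per-context miss rate and categorization accuracy
    p_miss = {
        c: float((sub["outcome"] == "go_miss").mean()) for c, sub in go.groupby("context")
    }
    accuracy = {}
    for c, sub in go.groupby("context"):
        r = sub[sub["outcome"].isin(RESPONDED_GO)]
        accuracy[c] = float((r["outcome"] == "go_correct").mean()) if len(r) else float("nan")

    # SSRT per stimulus type, stop contexts pooled
    stops = records[records["trial_kind"] == "stop"]
    stop_ctx = [c for c, p in probs.items() if p > 0 and (stops["context"] == c).any()]
    ssrt: dict = {}
    mean_ssd: dict = {}
    p_resp: dict = {}
    if len(stops):
        for stim in STIMULUS_TYPES:
            st_stops = stops[stops["stimulus_type"] == stim]
            if not len(st_stops):
                continue
            p = float((st_stops["outcome"] == "stop_respond").mean())
            msd = float(st_stops["ssd_ms"].mean())
            st_go = go[(go["stimulus_type"] == stim) & go["context"].isin(stop_ctx)]
            dist = st_go["rt_ms"].to_numpy(float)
            dist = np.where(np.isnan(dist), deadline_ms, dist)  # misses at the deadline
            mean_ssd[stim] = msd
            p_resp[stim] = p
            if p > 0 and dist.size:
                ssrt[stim] = estimate_ssrt_integration(dist, p, msd)
            else:
                ssrt[stim] = float("nan")

    excluded = False
    reason = None
    p_pooled = None
    mean_failed = None
    mean_go_rt = None
    if len(stops):
        diag = validity_checks(records)
        p_pooled = diag.p_respond_pooled
        mean_failed = diag.mean_failed_stop_rt
        mean_go_rt = diag.mean_go_rt
        if exclusion_check(p_pooled):
            excluded = True
            reason = (
                f"p[respond|signal] = {p_pooled:.2f} exceeds "
                f"{P_RESPOND_EXCLUSION:.0%} go responses on stop trials"
            )

    return SubjectSummary(
        subject_id=sid,
        group=grp,
        go_rt_mean=cell_means,
        go_rt_mean_context=ctx_means,
        proactive_slope_by_stimulus=slope_by_stim,
        proactive_slope_pooled=slope_pooled,
        ssrt=ssrt,
        mean_ssd=mean_ssd,
        p_respond_signal=p_resp,
        p_respond_pooled=p_pooled,
        mean_failed_stop_rt=mean_failed,
        mean_go_rt=mean_go_rt,
        p_miss=p_miss,
        accuracy=accuracy,
        excluded=excluded,
        exclusion_reason=reason,
    )


def summarize_cohort(trials: pd.DataFrame, deadline_ms: float = 1250.0) -> pd.DataFrame:
    """One flattened SubjectSummary row per subject in a cohort trial log."""
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        rows.append(summarize_subject(sub, deadline_ms=deadline_ms).to_row())
    return pd.DataFrame(rows)
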