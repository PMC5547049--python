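"""Horse-race simulation of subjects performing the stop-signal task.

Behavior follows the independent race model: on every trial a go process with
an ex-Gaussian finish time races the response deadline, and on stop trials it
additionally races a stop process that starts at the stop-signal delay (SSD)
and finishes a stop latency later. The subject responds on a stop trial iff
the go process finishes before both the stop process and the deadline.

Proactive control is additive slowing of the go process that grows linearly
with the context's nominal stop-signal probability. The SSD is tracked by a
1-up/1-down staircase (one per stimulus type, shared across the yellow,
orange and red contexts, initial value 800 ms, 25 ms steps): successful stops
raise the SSD, failed stops lower it, which drives the long-run probability
of responding on stop trials toward 0.50.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd

from .design import (
    CONTEXT_PROBABILITY,
    DesignSpec,
    STIMULUS_TYPES,
    build_schedule,
    default_design,
)

OUTCOMES = ("go_correct", "go_error", "go_miss", "stop_respond", "stop_inhibit")

TRIAL_LOG_COLUMNS = [
    "subject_id",
    "group",
    "trial_index",
    "block_index",
    "context",
    "trial_kind",
    "stimulus_type",
    "picture_id",
    "onset_ms",
    "ssd_ms",
    "rt_ms",
    "outcome",
]

PARAM_COLUMNS = [
    "subject_id",
    "group",
    "go_mu",
    "go_sigma",
    "go_tau",
    "proactive_gain",
    "stimulus_rt_offset",
    "ssrt_true_mu",
    "ssrt_true_sigma",
    "p_miss_lapse",
    "p_choice_error",
    "p_trigger_failure",
    "neural_covariate",
]


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one simulated subject.

    ``go_mu``, ``go_sigma``, ``go_tau`` parameterize the ex-Gaussian go
    finish time at stop probability 0; ``proactive_gain`` (ms per unit stop
    probability) shifts ``go_mu`` additively by ``gain * p_context``;
    ``stimulus_rt_offset`` is added on poker trials. The stop latency is
    normal(``ssrt_true_mu``, ``ssrt_true_sigma``) truncated at 0.
    ``p_trigger_failure`` is an extension point (probability the stop signal
    goes unprocessed); it defaults to 0.
    """

    subject_id: str
    group: str
    go_mu: float
    go_sigma: float
    go_tau: float
    proactive_gain: float
    ssrt_true_mu: float
    ssrt_true_sigma: float
    stimulus_rt_offset: float = 0.0
    p_miss_lapse: float = 0.0
    p_choice_error: float = 0.0
    p_trigger_failure: float = 0.0
    neural_covariate: float = float("nan")

    def __post_init__(self) -> None:
        if self.go_sigma <= 0:
            raise ValueError("go_sigma must be > 0")
        if self.go_tau < 0:
            raise ValueError("go_tau must be >= 0")
        if self.ssrt_true_mu <= 0:
            raise ValueError("ssrt_true_mu must be > 0")
        if self.ssrt_true_sigma < 0:
            raise ValueError("ssrt_true_sigma must be >= 0")
        for name in ("p_miss_lapse", "p_choice_error", "p_trigger_failure"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class StaircaseState:
    """Adaptive SSD tracker for one stimulus type."""

    stimulus_type: str
    current_ssd: float


def update_staircase(
    state: StaircaseState, inhibited: bool, step: float, ssd_max: float = 1250.0
) -> StaircaseState:
    """1-up/1-down SSD update: +step after a successful stop, -step after a
    failed one, clamped to [0, ssd_max]."""
    if step <= 0:
        raise ValueError("step must be > 0")
    ssd = state.current_ssd + (step if inhibited else -step)
    ssd = min(max(ssd, 0.0), ssd_max)
    return replace(state, current_ssd=ssd)


def _ex_gaussian(
    rng: np.random.Generator, mu, sigma: float, tau: float, size: int
) -> np.ndarray:
    g = rng.normal(mu, sigma, size=size)
    if tau > 0:
        g = g + rng.exponential(tau, size=size)
    return np.maximum(g, 1e-3)  # finish times are positive


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, size: int
) -> np.ndarray:
    """Normal truncated at 0 by rejection (negligible mass below 0 for
    realistic stop-latency parameters)."""
    s = rng.normal(mu, sigma, size=size)
    bad = s <= 0
    while bad.any():
        s[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = s <= 0
    return s


def simulate_trial(
    params: SubjectParams,
    plan: dict | pd.Series,
    staircase: StaircaseState,
    rng: np.random.Generator,
    design: DesignSpec | None = None,
) -> tuple[dict, StaircaseState]:
    """Simulate a single trial; returns (record, updated staircase).

    The staircase is only consulted and advanced on stop trials and must
    match the plan's stimulus type there. SSD is measured from picture onset
    and the stop signal is audible only while the picture is shown, so the
    staircase clamp equals the picture duration.
    """
    design = design or default_design()
    if plan["trial_kind"] == "stop" and staircase.stimulus_type != plan["stimulus_type"]:
        raise ValueError(
            f"staircase for {staircase.stimulus_type!r} used on a "
            f"{plan['stimulus_type']!r} stop trial"
        )
    p_ctx = design.stop_probability(plan["context"])
    mu = params.go_mu + params.proactive_gain * p_ctx
    if plan["stimulus_type"] == "poker":
        mu += params.stimulus_rt_offset
    g = float(_ex_gaussian(rng, mu, params.go_sigma, params.go_tau, 1)[0])
    lapse = rng.random() < params.p_miss_lapse
    deadline = design.picture_duration_ms

    record = dict(plan)
    record["ssd_ms"] = np.nan
    record["rt_ms"] = np.nan

    if plan["trial_kind"] == "go":
        if lapse or g > deadline:
            record["outcome"] = "go_miss"
        else:
            record["rt_ms"] = g
            err = rng.random() < params.p_choice_error
            record["outcome"] = "go_error" if err else "go_correct"
        return record, staircase

    ssd = staircase.current_ssd
    s = float(_truncated_normal(rng, params.ssrt_true_mu, params.ssrt_true_sigma, 1)[0])
    triggered = rng.random() >= params.p_trigger_failure
    responded = (not lapse) and g <= deadline and (g < ssd + s or not triggered)
    record["ssd_ms"] = ssd
    if responded:
        record["rt_ms"] = g
        record["outcome"] = "stop_respond"
    else:
        record["outcome"] = "stop_inhibit"
    new_state = update_staircase(
        staircase, inhibited=not responded, step=design.ssd_step_ms, ssd_max=deadline
    )
    return record, new_state


def simulate_subject(
    params: SubjectParams,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    design: DesignSpec | None = None,
) -> pd.DataFrame:
    """Simulate one subject over a full schedule.

    Go finish times, lapses and choice errors are drawn for all trials up
    front (they carry no sequential dependence); stop trials are then walked
    in schedule order so each stimulus type's staircase evolves on exactly
    its own stop trials.
    """
    design = design or default_design()
    n = len(schedule)
    deadline = design.picture_duration_ms

    p_ctx = schedule["context"].map(design.stop_probability).to_numpy(float)
    mu = params.go_mu + params.proactive_gain * p_ctx
    mu = mu + np.where(
        schedule["stimulus_type"].to_numpy() == "poker", params.stimulus_rt_offset, 0.0
    )
    g = _ex_gaussian(rng, mu, params.go_sigma, params.go_tau, n)
    lapse = rng.random(n) < params.p_miss_lapse
    choice_err = rng.random(n) < params.p_choice_error

    is_stop = (schedule["trial_kind"].to_numpy() == "stop")
    n_stop = int(is_stop.sum())
    s_lat = _truncated_normal(rng, params.ssrt_true_mu, params.ssrt_true_sigma, n_stop)
    triggered = rng.random(n_stop) >= params.p_trigger_failure

    ssd = np.full(n, np.nan)
    rt = np.full(n, np.nan)
    outcome = np.empty(n, dtype=object)

    # vectorized go trials
    go = ~is_stop
    go_miss = go & (lapse | (g > deadline))
    go_resp = go & ~go_miss
    outcome[go_miss] = "go_miss"
    outcome[go_resp] = np.where(choice_err[go_resp], "go_error", "go_correct")
    rt[go_resp] = g[go_resp]

    # sequential stop trials (staircase dependence)
    stair = {st: StaircaseState(st, float(design.ssd_initial_ms)) for st in STIMULUS_TYPES}
    stim_arr = schedule["stimulus_type"].to_numpy()
    for j, i in enumerate(np.flatnonzero(is_stop)):
        st = stair[stim_arr[i]]
        cur = st.current_ssd
        responded = (
            (not lapse[i])
            and g[i] <= deadline
            and (g[i] < cur + s_lat[j] or not triggered[j])
        )
        ssd[i] = cur
        if responded:
            rt[i] = g[i]
            outcome[i] = "stop_respond"
        else:
            outcome[i] = "stop_inhibit"
        stair[stim_arr[i]] = update_staircase(
            st, inhibited=not responded, step=design.ssd_step_ms, ssd_max=deadline
        )

    out = schedule.copy()
    out["ssd_ms"] = ssd
    out["rt_ms"] = rt
    out["outcome"] = outcome
    return out


@dataclass(frozen=True)
class GroupParamSpec:
    """Group-level sampling distributions for SubjectParams.

    Means/SDs are of normal distributions over subjects; scale parameters are
    truncated at small positive floors. Defaults reflect the study
    conditions: poker players categorize ~60 ms faster than controls at equal
    true SSRT (200 ms), proactive gain ~ N(600, 150) ms per unit stop
    probability, low lapse and categorization-error rates.
    """

    group: str
    go_mu_mean: float = 760.0
    go_mu_sd: float = 60.0
    go_sigma_mean: float = 60.0
    go_sigma_sd: float = 10.0
    go_tau_mean: float = 100.0
    go_tau_sd: float = 20.0
    proactive_gain_mean: float = 600.0
    proactive_gain_sd: float = 150.0
    stimulus_rt_offset_mean: float = 0.0
    stimulus_rt_offset_sd: float = 0.0
    ssrt_true_mu_mean: float = 200.0
    ssrt_true_mu_sd: float = 25.0
    ssrt_true_sigma: float = 30.0
    p_miss_lapse: float = 0.05
    p_choice_error: float = 0.02
    p_trigger_failure: float = 0.0


def default_group_specs() -> tuple[GroupParamSpec, GroupParamSpec]:
    return (
        GroupParamSpec(group="control"),
        GroupParamSpec(group="gambler", go_mu_mean=700.0),
    )


def sample_subject_params(
    spec: GroupParamSpec, subject_id: str, rng: np.random.Generator
) -> SubjectParams:
    """Draw one subject's generative parameters from group distributions."""
    return SubjectParams(
        subject_id=subject_id,
        group=spec.group,
        go_mu=rng.normal(spec.go_mu_mean, spec.go_mu_sd),
        go_sigma=max(rng.normal(spec.go_sigma_mean, spec.go_sigma_sd), 10.0),
        go_tau=max(rng.normal(spec.go_tau_mean, spec.go_tau_sd), 0.0),
        proactive_gain=max(rng.normal(spec.proactive_gain_mean, spec.proactive_gain_sd), 0.0),
        stimulus_rt_offset=(
            rng.normal(spec.stimulus_rt_offset_mean, spec.stimulus_rt_offset_sd)
            if spec.stimulus_rt_offset_sd > 0
            else spec.stimulus_rt_offset_mean
        ),
        ssrt_true_mu=max(rng.normal(spec.ssrt_true_mu_mean, spec.ssrt_true_mu_sd), 50.0),
        ssrt_true_sigma=spec.ssrt_true_sigma,
        p_miss_lapse=spec.p_miss_lapse,
        p_choice_error=spec.p_choice_error,
        p_trigger_failure=spec.p_trigger_failure,
    )


def _proactive_slope_of(trials: pd.DataFrame, design: DesignSpec) -> float:
    """Realized proactive slope of one subject's simulated log (OLS of
    context mean go RT on nominal stop probability; no outlier filter here —
    this is the generator's own summary used for covariate coupling)."""
    resp = trials[trials["outcome"].isin(["go_correct", "go_error"])]
    means = resp.groupby("context")["rt_ms"].mean()
    p = np.array([design.stop_probability(c) for c in means.index])
    y = means.to_numpy(float)
    return float(np.polyfit(p, y, 1)[0])


def attach_neural_covariate(
    params_table: pd.DataFrame,
    slopes: np.ndarray,
    rng: np.random.Generator,
    target_spearman: float = -0.47,
) -> pd.DataFrame:
    """Generate a per-subject scalar covariate with a Gaussian-copula rank
    correlation of ``target_spearman`` against the realized proactive slope.

    The slope ranks are mapped to normal scores; the covariate is drawn
    jointly normal with them at the Pearson correlation 2*sin(pi*rho_s/6),
    which makes the pair's population Spearman correlation equal the target.
    """
    from scipy import stats

    n = len(slopes)
    rho_p = 2.0 * np.sin(np.pi * target_spearman / 6.0)
    ranks = stats.rankdata(slopes)
    z1 = stats.norm.ppf(ranks / (n + 1.0))
    z2 = rho_p * z1 + np.sqrt(1.0 - rho_p**2) * rng.normal(size=n)
    out = params_table.copy()
    out["neural_covariate"] = z2
    return out


def simulate_cohort(
    n_per_group: int,
    group_param_specs: tuple[GroupParamSpec, ...] | None = None,
    design: DesignSpec | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    copula_target: float | None = -0.47,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group cohort; returns (trial log, subject params).

    Each subject gets freshly sampled parameters and a freshly randomized
    schedule. When ``copula_target`` is set, a neural covariate rank-
    correlated with each subject's realized proactive slope at that target is
    added to the parameter table (the stand-in for the dACC parameter
    estimates of the source study design).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    design = design or default_design()
    specs = group_param_specs or default_group_specs()

    logs = []
    params_rows = []
    slopes = []
    i = 0
    for spec in specs:
        for _ in range(n_per_group):
            i += 1
            sid = f"s{i:03d}"
            p = sample_subject_params(spec, sid, rng)
            schedule = build_schedule(design, rng)
            trials = simulate_subject(p, schedule, rng, design)
            trials.insert(0, "group", p.group)
            trials.insert(0, "subject_id", sid)
            logs.append(trials)
            params_rows.append(asdict(p))
            slopes.append(_proactive_slope_of(trials, design))

    log = pd.concat(logs, ignore_index=True)[TRIAL_LOG_COLUMNS]
    params = pd.DataFrame(params_rows)[PARAM_COLUMNS]
    if copula_target is not None:
        params = attach_neural_covariate(params, np.array(slopes), rng, copula_target)
    return log, params
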