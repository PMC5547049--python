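"""End-to-end study analysis as a model/results pair.

``StopSignalStudy`` wraps a tidy per-trial log (simulated or observed) and,
on ``fit()``, runs the full behavioral chain: per-subject summaries with
outlier filtering, validity diagnostics and exclusion rules, then the
group-level inference — the proactive ANOVA (context x stimulus x group on
go RT), the reactive ANOVA (stimulus x group on SSRT), pairwise context
comparisons, and Spearman correlations of an optional per-subject covariate
with the proactive slope, SSRT and p[respond|signal] (Bonferroni-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONTEXT_ORDER, STIMULUS_TYPES
from .group_stats import (
    CorrResult,
    MixedAnova,
    MixedAnovaResults,
    pairwise_context_tests,
    spearman,
)
from .metrics import summarize_cohort, validity_checks


def _melt_go_rt(summary: pd.DataFrame) -> pd.DataFrame:
    """Long (subject, group, context, stimulus, go_rt) table from the
    flattened subject-summary frame."""
    rows = []
    for _, r in summary.iterrows():
        for ctx in CONTEXT_ORDER:
            for stim in STIMULUS_TYPES:
                col = f"go_rt_{ctx}_{stim}"
                if col in summary.columns:
                    rows.append({
                        "subject_id": r["subject_id"], "group": r["group"],
                        "context": ctx, "stimulus_type": stim, "go_rt": r[col],
                    })
    return pd.DataFrame(rows)


def _melt_ssrt(summary: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in summary.iterrows():
        for stim in STIMULUS_TYPES:
            col = f"ssrt_{stim}"
            if col in summary.columns:
                rows.append({
                    "subject_id": r["subject_id"], "group": r["group"],
                    "stimulus_type": stim, "ssrt": r[col],
                })
    return pd.DataFrame(rows)


class StopSignalStudy:
    """Behavioral analysis model for one stop-signal task cohort.

    Parameters
    ----------
    trials : tidy per-trial log (one row per trial, columns as written by
        the simulator / the trial-log CSV schema).
    covariates : optional per-subject frame with ``subject_id`` and a scalar
        covariate column (e.g. a neural parameter estimate) to correlate
        with the behavioral measures.
    covariate_col : name of that column (default ``neural_covariate``).
    """

    def __init__(self, trials: pd.DataFrame, covariates: pd.DataFrame | None = None,
                 covariate_col: str = "neural_covariate"):
        required = {"subject_id", "group", "context", "trial_kind", "stimulus_type",
                    "rt_ms", "outcome"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial log is missing columns: {sorted(missing)}")
        self.trials = trials
        self.covariates = covariates
        self.covariate_col = covariate_col

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, **kw) -> "StopSignalStudy":
        return cls(trials, **kw)

    def fit(self, anova: bool = True) -> "StopSignalStudyResults":
        summary = summarize_cohort(self.trials)
        excluded = summary[summary["excluded"]]
        retained = summary[~summary["excluded"]].reset_index(drop=True)
        if retained.empty:
            raise ValueError("all subjects excluded; nothing to analyze")

        # per-subject validity table (kept subjects)
        validity = retained[[
            "subject_id", "group", "p_respond_pooled",
            "mean_failed_stop_rt", "mean_go_rt",
        ]].copy()
        validity["independence_ok"] = (
            validity["mean_failed_stop_rt"] < validity["mean_go_rt"]
        )

        proactive = reactive = None
        pairwise = None
        n_groups = retained["group"].nunique()
        if anova:
            go_long = _melt_go_rt(retained).dropna(subset=["go_rt"])
            proactive = MixedAnova(
                go_long, dv="go_rt", within=["context", "stimulus_type"],
                between="group" if n_groups > 1 else None,
            ).fit()
            ssrt_long = _melt_ssrt(retained).dropna(subset=["ssrt"])
            if len(ssrt_long):
                reactive = MixedAnova(
                    ssrt_long, dv="ssrt", within=["stimulus_type"],
                    between="group" if n_groups > 1 else None,
                ).fit()
            ctx_means = retained.set_index("subject_id")[
                [f"go_rt_{c}" for c in CONTEXT_ORDER]
            ]
            ctx_means.columns = list(CONTEXT_ORDER)
            pairwise = pairwise_context_tests(ctx_means)

        correlations = None
        if self.covariates is not None:
            cov = retained.merge(
                self.covariates[["subject_id", self.covariate_col]], on="subject_id"
            )
            targets = {
                "proactive_slope": cov["proactive_slope_pooled"],
                "ssrt": cov[[f"ssrt_{s}" for s in STIMULUS_TYPES]].mean(axis=1),
                "p_respond": cov["p_respond_pooled"],
            }
            rows = []
            for name, vals in targets.items():
                ok = vals.notna() & cov[self.covariate_col].notna()
                r = spearman(cov.loc[ok, self.covariate_col], vals[ok],
                             n_comparisons=len(targets))
                rows.append({"measure": name, "rho": r.rho, "n": r.n,
                             "p": r.p, "p_bonferroni": r.p_adjusted})
            correlations = pd.DataFrame(rows)

        return StopSignalStudyResults(
            model=self, subject_summaries=summary, retained=retained,
            excluded=excluded, validity=validity, proactive_anova=proactive,
            reactive_anova=reactive, pairwise_contexts=pairwise,
            correlations=correlations,
        )


@dataclass
class StopSignalStudyResults:
    """Fitted cohort analysis: subject summaries, diagnostics, inference."""

    model: StopSignalStudy
    subject_summaries: pd.DataFrame
    retained: pd.DataFrame
    excluded: pd.DataFrame
    validity: pd.DataFrame
    proactive_anova: MixedAnovaResults | None
    reactive_anova: MixedAnovaResults | None
    pairwise_contexts: pd.DataFrame | None
    correlations: pd.DataFrame | None

    def summary(self) -> str:
        lines = ["Stop-signal task cohort analysis", "=" * 34]
        n = len(self.subject_summaries)
        lines.append(f"subjects: {n} ({len(self.retained)} retained, "
                     f"{len(self.excluded)} excluded)")
        for _, r in self.excluded.iterrows():
            lines.append(f"  excluded {r['subject_id']}: {r['exclusion_reason']}")
        v = self.validity
        lines += [
            "",
            "Validity (retained subjects, stop contexts pooled)",
            f"  mean p[respond|signal]: {v['p_respond_pooled'].mean():.3f}",
            f"  mean failed-stop RT:    {v['mean_failed_stop_rt'].mean():.1f} ms",
            f"  mean go RT:             {v['mean_go_rt'].mean():.1f} ms",
            f"  independence (failed < go) holds for "
            f"{int(v['independence_ok'].sum())}/{len(v)} subjects",
        ]
        for ctx in CONTEXT_ORDER:
            col = f"go_rt_{ctx}"
            if col in self.retained:
                lines.append(f"  mean go RT [{ctx:<6}]:   "
                             f"{self.retained[col].mean():.1f} ms")
        lines.append(f"  mean proactive slope:   "
                     f"{self.retained['proactive_slope_pooled'].mean():.1f} ms/unit p")
        for stim in STIMULUS_TYPES:
            col = f"ssrt_{stim}"
            if col in self.retained:
                lines.append(f"  mean SSRT [{stim:<7}]:    "
                             f"{self.retained[col].mean():.1f} ms")
        if self.proactive_anova is not None:
            lines += ["", "Proactive inhibition (go RT)",
                      self.proactive_anova.summary()]
        if self.pairwise_contexts is not None:
            lines += ["", f"context ordering by mean RT: "
                      f"{self.pairwise_contexts.attrs.get('ordering', '')}"]
        if self.reactive_anova is not None:
            lines += ["", "Reactive inhibition (SSRT)", self.reactive_anova.summary()]
        if self.correlations is not None:
            lines += ["", "Covariate correlations (Spearman, Bonferroni-adjusted)"]
            for _, r in self.correlations.iterrows():
                lines.append(f"  {r['measure']:<16} rho({r['n']:.0f}) = {r['rho']:+.2f}, "
                             f"p = {r['p']:.3f}, p_adj = {r['p_bonferroni']:.3f}")
        return "\n".join(lines)
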