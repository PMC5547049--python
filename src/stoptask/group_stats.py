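"""Group-level inference: mixed (split-plot) repeated-measures ANOVA,
pairwise context comparisons, Spearman correlation, Bonferroni adjustment.

The ANOVA handles balanced designs with any number of fully crossed
within-subject factors and at most one between-subjects factor, using the
classical marginal-means (Yates) sums-of-squares decomposition. Error terms
follow the split-plot convention: the between factor is tested against
subjects-within-groups, each within effect (and its interaction with the
between factor) against its own effect-by-subjects-within-groups term.
Effect sizes are partial eta squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA (statsmodels-style Model / Results pair)
# ---------------------------------------------------------------------------


class MixedAnova:
    """Balanced mixed repeated-measures ANOVA model.

    Parameters
    ----------
    data : long-format DataFrame with one row per (subject, within-cell).
    dv : name of the dependent-variable column.
    within : list of within-subject factor columns (fully crossed).
    between : optional between-subjects factor column (constant per subject).
    subject : subject-identifier column.

    The design must be complete and balanced: every subject contributes
    exactly one observation per within-cell. Missing or duplicated cells
    raise; no imputation is attempted.
    """

    def __init__(self, data: pd.DataFrame, dv: str, within, between: str | None = None,
                 subject: str = "subject_id"):
        self.data = data
        self.dv = dv
        self.within = list(within)
        self.between = between
        self.subject = subject
        self._validate()

    def _validate(self) -> None:
        d = self.data
        for col in [self.dv, self.subject, *self.within] + ([self.between] if self.between else []):
            if col not in d.columns:
                raise ValueError(f"column {col!r} not in data")
        if d[self.dv].isna().any():
            raise ValueError("dependent variable contains missing values")
        counts = d.groupby([self.subject, *self.within], observed=True).size()
        if (counts != 1).any():
            bad = counts[counts != 1]
            raise ValueError(
                "design is not balanced/complete: expected exactly one observation "
                f"per (subject, within-cell); offending cells: {bad.index.tolist()[:5]}"
            )
        q = int(np.prod([d[w].nunique() for w in self.within])) if self.within else 1
        per_subject = d.groupby(self.subject, observed=True).size()
        if (per_subject != q).any():
            raise ValueError("some subjects are missing within-cells (incomplete design)")
        if self.between is not None:
            g = d.groupby(self.subject, observed=True)[self.between].nunique()
            if (g != 1).any():
                raise ValueError("between factor must be constant within subject")
            n_per_group = d.drop_duplicates(self.subject).groupby(
                self.between, observed=True
            ).size()
            if (n_per_group < 2).any():
                raise ValueError("need >= 2 subjects per group")

    # -- sums of squares ----------------------------------------------------

    def _margin_ss(self, cols: tuple[str, ...], d: pd.DataFrame, grand: float) -> float:
        """S(M) = sum over observations of (margin-cell mean - grand)^2."""
        if not cols:
            return 0.0
        m = d.groupby(list(cols), observed=True)[self.dv].transform("mean")
        return float(((m - grand) ** 2).sum())

    def fit(self, gg_correction: bool = False) -> "MixedAnovaResults":
        d = self.data
        y = d[self.dv].to_numpy(float)
        grand = y.mean()
        n_subjects = d[self.subject].nunique()
        a = d[self.between].nunique() if self.between else 1
        levels = {w: d[w].nunique() for w in self.within}

        S = lambda *cols: self._margin_ss(tuple(cols), d, grand)
        gcols = (self.between,) if self.between else ()

        def yates(subsets_of: list[str], extra: tuple[str, ...]) -> float:
            """Sum_{F' subset F} (-1)^(|F|-|F'|) S(F' + extra)."""
            k = len(subsets_of)
            total = 0.0
            for r in range(k + 1):
                for sub in itertools.combinations(subsets_of, r):
                    total += (-1) ** (k - r) * S(*sub, *extra)
            return total

        rows = []

        # between-subjects stratum
        ss_subj_total = S(self.subject)
        if self.between:
            ss_g = S(self.between)
            ss_subj = ss_subj_total - ss_g
            df_g, df_subj = a - 1, n_subjects - a
            rows.append(("group" if self.between == "group" else self.between,
                         ss_g, df_g, ss_subj, df_subj, None))
        else:
            ss_subj = ss_subj_total
            df_subj = n_subjects - 1

        # within-subject strata
        for r in range(1, len(self.within) + 1):
            for eff in itertools.combinations(self.within, r):
                eff = list(eff)
                df_eff = int(np.prod([levels[w] - 1 for w in eff]))
                ss_eff = yates(eff, ())
                ss_err = yates(eff, (self.subject,)) - yates(eff, gcols)
                df_err = df_eff * (n_subjects - a)
                rows.append((" * ".join(eff), ss_eff, df_eff, ss_err, df_err, tuple(eff)))
                if self.between:
                    ss_int = yates(eff, gcols) - yates(eff, ())
                    rows.append((" * ".join(eff + [self.between]),
                                 ss_int, df_eff * (a - 1), ss_err, df_err, tuple(eff)))

        eps = {}
        if gg_correction and self.within:
            eps = self._gg_epsilons(levels)

        out = []
        for name, ss, df1, ss_err, df2, within_key in rows:
            ms, ms_err = ss / df1, ss_err / df2
            f = ms / ms_err if ms_err > 0 else np.inf
            p = float(stats.f.sf(f, df1, df2))
            rec = {
                "effect": name, "ss": ss, "df1": df1, "df2": df2,
                "F": f, "p": p,
                "partial_eta_sq": ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0,
            }
            if gg_correction:
                e = eps.get(within_key, np.nan)
                rec["gg_eps"] = e
                rec["p_gg"] = (
                    float(stats.f.sf(f, df1 * e, df2 * e)) if np.isfinite(e) else p
                )
            out.append(rec)
        table = pd.DataFrame(out).set_index("effect")
        return MixedAnovaResults(self, table)

    def _gg_epsilons(self, levels: dict) -> dict:
        """Greenhouse-Geisser epsilon per within effect (and its interactions
        with the between factor), from the pooled within-group covariance of
        subject scores on orthonormal effect contrasts."""
        d = self.data
        wide = d.pivot_table(index=self.subject, columns=self.within, values=self.dv,
                             observed=True)
        wide = wide.sort_index(axis=1)
        X = wide.to_numpy(float)
        if self.between:
            groups = d.drop_duplicates(self.subject).set_index(self.subject)[self.between]
            groups = groups.loc[wide.index]
            Xc = X - np.stack([X[(groups == g).to_numpy()].mean(axis=0)
                               for g in groups])
            ddof = groups.nunique()
        else:
            Xc = X - X.mean(axis=0)
            ddof = 1
        cov = Xc.T @ Xc / (X.shape[0] - ddof)

        def contrasts(m: int) -> np.ndarray:
            # orthonormal (m-1) x m contrast rows
            h = np.eye(m) - np.ones((m, m)) / m
            q, _ = np.linalg.qr(h)
            return q[:, : m - 1].T

        ordered = sorted(self.within, key=lambda w: self.within.index(w))
        eps = {}
        for r in range(1, len(ordered) + 1):
            for eff in itertools.combinations(ordered, r):
                mats = []
                # column MultiIndex level order follows self.within
                for w in self.within:
                    m = levels[w]
                    mats.append(contrasts(m) if w in eff else np.ones((1, m)) / m)
                C = mats[0]
                for mtx in mats[1:]:
                    C = np.kron(C, mtx)
                V = C @ cov @ C.T
                k = V.shape[0]
                tr = np.trace(V)
                eps[tuple(eff)] = float(tr**2 / (k * np.trace(V @ V))) if k else np.nan
        return eps


@dataclass
class MixedAnovaResults:
    """Fitted mixed ANOVA: effect table plus a text summary."""

    model: MixedAnova
    anova_table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.anova_table.loc[name]

    def summary(self) -> str:
        lines = [
            "Mixed repeated-measures ANOVA",
            f"  dv: {self.model.dv}; within: {self.model.within}; "
            f"between: {self.model.between}",
            "",
            f"{'effect':<28}{'F':>10}{'df':>12}{'p':>10}{'partial eta^2':>16}",
        ]
        for name, r in self.anova_table.iterrows():
            lines.append(
                f"{name:<28}{r['F']:>10.2f}{f'({r.df1:.0f}, {r.df2:.0f})':>12}"
                f"{r['p']:>10.4f}{r['partial_eta_sq']:>16.3f}"
            )
        return "\n".join(lines)


def mixed_rm_anova(data: pd.DataFrame, dv: str, within, between: str | None = None,
                   subject: str = "subject_id", gg_correction: bool = False) -> pd.DataFrame:
    """Functional wrapper: fit a MixedAnova and return its effect table."""
    return MixedAnova(data, dv, within, between, subject).fit(gg_correction).anova_table


# ---------------------------------------------------------------------------
# Pairwise comparisons, Spearman, Bonferroni
# ---------------------------------------------------------------------------


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: each p multiplied by m (default: number of
    tests), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(p * m, 1.0)


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return math.copysign(math.inf, d.mean()), n - 1, 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def pairwise_context_tests(context_means: pd.DataFrame) -> pd.DataFrame:
    """All pairwise paired t-tests between context mean RTs.

    ``context_means``: one row per subject, one column per context. Returns a
    table with t, df, raw and Bonferroni-adjusted p per pair, plus the
    grand-mean ordering of contexts (slowest first) in ``attrs['ordering']``.
    """
    if len(context_means) < 2:
        raise ValueError("need >= 2 subjects for paired comparisons")
    cols = list(context_means.columns)
    rows = []
    for c1, c2 in itertools.combinations(cols, 2):
        t, df, p = _paired_t(context_means[c1].to_numpy(float),
                             context_means[c2].to_numpy(float))
        rows.append({"context_a": c1, "context_b": c2,
                     "mean_a": context_means[c1].mean(),
                     "mean_b": context_means[c2].mean(),
                     "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].to_numpy(), m=len(out))
    ordering = context_means.mean().sort_values(ascending=False)
    out.attrs["ordering"] = " > ".join(ordering.index)
    return out


@dataclass(frozen=True)
class CorrResult:
    """Spearman rank correlation with (optionally adjusted) p-value."""

    rho: float
    n: int
    p: float
    p_adjusted: float
    undefined_variance: bool = False


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates all permutations of one rank vector; handles ties because the
    statistic is the Pearson correlation of (average) ranks.
    """
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = math.sqrt(float(rxc @ rxc)) * np.sqrt((ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, n_comparisons: int = 1) -> CorrResult:
    """Spearman rank correlation (average ranks for ties).

    p-values use the exact permutation distribution for n <= 9 and the
    t approximation otherwise; ``p_adjusted`` is Bonferroni over
    ``n_comparisons`` tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrResult(float("nan"), n, float("nan"), float("nan"),
                          undefined_variance=True)
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 9:
        p = _spearman_exact_p(stats.rankdata(x), stats.rankdata(y), rho)
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2)) if abs(rho) < 1 else math.inf
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrResult(rho, n, p, float(bonferroni([p], m=n_comparisons)[0]))
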