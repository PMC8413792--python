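"""Repeated-measures statistics for the sleep x task connectivity design.

Network metrics are collected per subject in a fully crossed within-subject
design: sleep state (before/after sleep deprivation) x task state (rest and
six finger-tapping stimuli), optionally with the threshold parameter as a
third within factor.  This module provides:

* a balanced within-subject ANOVA for any number of crossed within factors,
  with Greenhouse-Geisser sphericity correction and Mauchly's test;
* Dunnett's many-to-one post hoc comparisons of task states against rest,
  with the adjustment evaluated by Monte-Carlo sampling of the correlated
  multivariate-t null;
* the Delta-WD statistic (change, after vs. before sleep deprivation, of the
  task-minus-rest global connection strength) and its correlation with
  cognitive-score changes;
* Kendall's coefficient of concordance across subjects' channel rankings;
* channel-wise paired-t contrast maps with Benjamini-Hochberg FDR control.

All tests assume one observation per subject per design cell (metrics are
deterministic functions of a session, so there is no within-cell
replication).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .montage import SLEEP_STATES, TASK_STATES

COGNITIVE_TESTS = ("PAL", "RTI", "RVPA")


@dataclass
class CohortResults:
    """Long table of per-subject, per-cell network metrics.

    Columns: subject, sleep_state, task_state, scheme, parameter, metric,
    value (one row per combination).
    """

    table: pd.DataFrame
    log_transformed: bool = False

    def select(self, scheme: str, metric: str,
               parameter: float | None = None) -> pd.DataFrame:
        t = self.table
        mask = (t["scheme"] == scheme) & (t["metric"] == metric)
        if parameter is not None:
            mask &= np.isclose(t["parameter"].astype(float), parameter)
        return t.loc[mask].copy()


def log_transform(results: CohortResults, epsilon: float = 1e-6) -> CohortResults:
    """log(value + epsilon); network densities are nonnegative but can be 0."""
    if results.log_transformed:
        raise ValueError("results are already log-transformed")
    if (results.table["value"] < 0).any():
        raise ValueError("cannot log-transform negative metric values")
    out = results.table.copy()
    out["value"] = np.log(out["value"] + epsilon)
    return CohortResults(table=out, log_transformed=True)


# ---------------------------------------------------------------------------
# balanced fully-within-subject ANOVA


@dataclass
class EffectResult:
    """One ANOVA effect: F test plus sphericity diagnostics."""

    ss: float
    ss_error: float
    df_num: int
    df_den: int
    f: float
    p: float
    gg_epsilon: float
    p_gg: float
    mauchly_w: float
    mauchly_p: float

    @property
    def p_reported(self) -> float:
        """Sphericity-corrected p when Mauchly rejects, raw p otherwise."""
        if np.isfinite(self.mauchly_p) and self.mauchly_p < 0.05:
            return self.p_gg
        return self.p


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    factor_levels: dict[str, list]
    n_subjects: int
    shapiro_p: pd.DataFrame | None = None

    def __getitem__(self, effect: str) -> EffectResult:
        return self.effects[effect]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the mean-zero subspace (Helmert-like)."""
    h = np.eye(k) - np.full((k, k), 1.0 / k)
    q, r = np.linalg.qr(h)
    return q[:, : k - 1]


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, ...] = ("sleep_state", "task_state"),
    subject: str = "subject",
) -> AnovaResult:
    """Balanced fully crossed within-subject ANOVA (any number of factors).

    Sums of squares follow the standard balanced-factorial decomposition;
    each within effect is tested against its interaction with subjects.
    Greenhouse-Geisser epsilon and Mauchly's sphericity test are computed
    from the covariance of orthonormally contrast-transformed subject
    scores; both raw and epsilon-corrected p-values are returned.
    """
    levels = {f: list(pd.unique(data[f])) for f in within}
    subjects = list(pd.unique(data[subject]))
    n = len(subjects)
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    shape = [n] + [len(levels[f]) for f in within]
    y = np.full(shape, np.nan)
    sub_idx = {s: i for i, s in enumerate(subjects)}
    lev_idx = [{v: i for i, v in enumerate(levels[f])} for f in within]
    for _, row in data.iterrows():
        idx = (sub_idx[row[subject]],) + tuple(
            lev_idx[k][row[f]] for k, f in enumerate(within)
        )
        y[idx] = row[dv]
    if np.isnan(y).any():
        missing = int(np.isnan(y).sum())
        raise ValueError(f"incomplete design: {missing} empty cells")

    all_axes = tuple(range(y.ndim))  # axis 0 = subject, axes 1.. = factors

    def r_term(axes_kept: tuple[int, ...]) -> float:
        """Sum over kept-cell totals squared, divided by obs per cell."""
        drop = tuple(a for a in all_axes if a not in axes_kept)
        totals = y.sum(axis=drop) if drop else y
        per_cell = y.size / totals.size
        return float((np.asarray(totals) ** 2).sum() / per_cell)

    def ss_for(axes: tuple[int, ...]) -> float:
        ss = 0.0
        for k in range(len(axes) + 1):
            for sub in itertools.combinations(axes, k):
                ss += (-1) ** (len(axes) - k) * r_term(sub)
        return ss

    effects: dict[str, EffectResult] = {}
    factor_axes = {f: i + 1 for i, f in enumerate(within)}
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(within, k):
            axes = tuple(factor_axes[f] for f in combo)
            ss = ss_for(axes)
            ss_err = ss_for((0,) + axes)
            df_num = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df_den = df_num * (n - 1)
            if ss_err <= 0 or df_den == 0:
                raise ValueError(
                    f"degenerate error variance for effect {'*'.join(combo)}"
                )
            f_stat = (ss / df_num) / (ss_err / df_den)
            p = float(sstats.f.sf(f_stat, df_num, df_den))
            eps, mw, mp = _sphericity(y, axes, within, levels, combo)
            p_gg = float(sstats.f.sf(f_stat, df_num * eps, df_den * eps))
            effects["*".join(combo)] = EffectResult(
                ss=ss, ss_error=ss_err, df_num=df_num, df_den=df_den,
                f=f_stat, p=p, gg_epsilon=eps, p_gg=p_gg,
                mauchly_w=mw, mauchly_p=mp,
            )
    return AnovaResult(effects=effects, factor_levels=levels, n_subjects=n)


def _sphericity(y, axes, within, levels, combo):
    """GG epsilon and Mauchly test for one effect's contrast covariance."""
    n = y.shape[0]
    other = tuple(a for a in range(1, y.ndim) if a not in axes)
    ysub = y.mean(axis=other) if other else y
    ysub = ysub.reshape(n, -1)  # subjects x effect cells
    c = np.ones((1, 1))
    for f in combo:
        c = np.kron(c, _orthonormal_contrasts(len(levels[f])))
    d = c.shape[1]
    if d == 1:
        return 1.0, 1.0, 1.0
    t = ysub @ c
    sigma = np.cov(t, rowvar=False)
    tr = np.trace(sigma)
    tr2 = np.trace(sigma @ sigma)
    eps = (tr**2) / (d * tr2) if tr2 > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / d, 1.0))
    if n - 1 <= d:
        return eps, np.nan, np.nan  # covariance singular: Mauchly undefined
    det = np.linalg.det(sigma)
    if det <= 0 or tr <= 0:
        return eps, 0.0, 0.0
    w = float(det / (tr / d) ** d)
    dfc = d * (d + 1) // 2 - 1
    fcorr = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * fcorr * math.log(w)
    return eps, w, float(sstats.chi2.sf(chi2, dfc))


def shapiro_per_cell(
    data: pd.DataFrame, dv: str = "value",
    within: tuple[str, ...] = ("sleep_state", "task_state"),
) -> pd.DataFrame:
    """Shapiro-Wilk normality p per design cell (across subjects)."""
    rows = []
    for key, grp in data.groupby(list(within), sort=False):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp[dv].to_numpy(dtype=float)
        if len(vals) >= 3 and np.ptp(vals) > 0:
            p = float(sstats.shapiro(vals).pvalue)
        else:
            p = np.nan
        rows.append(dict(zip(within, key), shapiro_p=p, n=len(vals)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons against rest


def dunnett_vs_rest(
    data: pd.DataFrame,
    sleep_state: str,
    dv: str = "value",
    n_draws: int = 100_000,
    seed: int = 2021,
) -> pd.DataFrame:
    """Task states vs. rest within one sleep state, Dunnett-adjusted.

    Paired contrasts d_k = Stim_k - Rest are formed per subject; the
    adjusted p of contrast k is P(max_j |T_j| >= |t_k|) under a correlated
    multivariate-t null whose correlation is estimated from the contrast
    scores (Monte-Carlo with a fixed seed, shared chi-square scale).  With
    a single contrast this reduces to the paired two-sided t-test.
    """
    d = data[data["sleep_state"] == sleep_state]
    wide = d.pivot_table(index="subject", columns="task_state", values=dv)
    if "Rest" not in wide.columns:
        raise ValueError(f"no Rest cell in sleep state {sleep_state!r}")
    tasks = [c for c in TASK_STATES if c != "Rest" and c in wide.columns]
    if wide.shape[0] < 2:
        raise ValueError("Dunnett comparisons need at least 2 subjects")
    diffs = wide[tasks].to_numpy() - wide[["Rest"]].to_numpy()
    n, k = diffs.shape
    mean = diffs.mean(axis=0)
    se = diffs.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(se > 0, mean / se, np.where(mean == 0, 0.0, np.inf))
    p_raw = 2.0 * sstats.t.sf(np.abs(t_obs), df=n - 1)

    sd = diffs.std(axis=0, ddof=1)
    ok = sd > 0
    corr = np.eye(k)
    if ok.sum() >= 2:
        sub = np.corrcoef(diffs[:, ok], rowvar=False)
        corr[np.ix_(np.where(ok)[0], np.where(ok)[0])] = sub
    # eigenvalue-clip in case the estimate is indefinite
    vals, vecs = np.linalg.eigh(corr)
    corr = (vecs * np.maximum(vals, 1e-10)) @ vecs.T
    dscale = np.sqrt(np.diag(corr))
    corr = corr / np.outer(dscale, dscale)

    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(k), corr, size=n_draws,
                                method="cholesky")
    s = rng.chisquare(n - 1, size=n_draws)
    tmax = np.abs(z / np.sqrt(s / (n - 1))[:, None]).max(axis=1)
    p_adj = np.array([
        1.0 if not np.isfinite(t) and t == 0 else float(np.mean(tmax >= abs(t)))
        for t in t_obs
    ])
    p_adj = np.minimum(1.0, np.maximum(p_adj, p_raw))  # adjustment is monotone
    return pd.DataFrame({
        "task_state": tasks, "mean_diff": mean, "t": t_obs,
        "p_unadjusted": p_raw, "p_adjusted": p_adj,
    })


# ---------------------------------------------------------------------------
# Delta-WD and brain-behaviour correlation


@dataclass
class DeltaWD:
    """Per-subject change of the task-related global connection strength.

    For each sleep state, WDbar = mean over the six stimuli of the global
    weighted density minus its resting value; delta = WDbar(after SD) -
    WDbar(before SD).
    """

    per_subject: pd.DataFrame  # columns: subject, wd_before, wd_after, delta


def delta_wd(data: pd.DataFrame, dv: str = "value") -> DeltaWD:
    """Compute Delta-WD from a long table of global weighted densities."""
    wide = data.pivot_table(index="subject", columns=["sleep_state", "task_state"],
                            values=dv)
    need = [(sl, ts) for sl in SLEEP_STATES for ts in TASK_STATES]
    missing = [c for c in need if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(f"missing design cells for Delta-WD: {missing}")
    out = {}
    for sl in SLEEP_STATES:
        stims = wide[[(sl, t) for t in TASK_STATES if t != "Rest"]].mean(axis=1)
        out[sl] = stims - wide[(sl, "Rest")]
    per = pd.DataFrame({
        "subject": wide.index,
        "wd_before": out["before_SD"].to_numpy(),
        "wd_after": out["after_SD"].to_numpy(),
    })
    per["delta"] = per["wd_after"] - per["wd_before"]
    return DeltaWD(per_subject=per.reset_index(drop=True))


def score_changes(scores: pd.DataFrame) -> pd.DataFrame:
    """Visit-2 minus visit-1 change per subject for each cognitive test."""
    v1 = scores[scores["visit"] == 1].set_index("subject_id")
    v2 = scores[scores["visit"] == 2].set_index("subject_id")
    out = pd.DataFrame(index=v1.index.union(v2.index))
    for test in COGNITIVE_TESTS:
        out[test] = v2[test] - v1[test]
    out.index.name = "subject"
    return out.reset_index()


def brain_behavior_correlation(
    delta: DeltaWD, changes: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (uncorrected two-sided p) between Delta-WD and score changes.

    Subjects missing a given score are dropped pairwise, so each test keeps
    its own n.
    """
    merged = delta.per_subject.merge(changes, on="subject", how="inner")
    rows = []
    for test in COGNITIVE_TESTS:
        if test not in merged.columns:
            continue
        sub = merged[["delta", test]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 paired observations for {test}")
        r, p = sstats.pearsonr(sub["delta"], sub[test])
        rows.append({"test": test, "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concordance and channel-wise maps


def kendalls_w(scores: np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``scores`` is (raters, items); raw scores are converted to within-rater
    ranks (average ranks on ties).  W = 1 means identical rankings, 0 means
    no agreement.
    """
    scores = np.asarray(scores, dtype=float)
    m, n = scores.shape
    if m < 2:
        raise ValueError("concordance needs at least 2 raters")
    ranks = np.apply_along_axis(sstats.rankdata, 1, scores)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        return 1.0  # all items tied within every rater
    return float(12.0 * s / denom)


CONTRASTS = ("task_minus_rest_before", "task_minus_rest_after", "sd_effect")


def channelwise_contrast_map(
    local_wd: np.ndarray, contrast: str
) -> pd.DataFrame:
    """Paired t contrast per channel with Benjamini-Hochberg FDR correction.

    ``local_wd`` has shape (subject, sleep, task, channel) where sleep index
    0/1 = before/after SD and task index 0 = rest, 1.. = stimuli.  The
    contrasts test whether the task-average minus rest local connection
    strength differs from 0 (per sleep state), or differs between sleep
    states (``sd_effect``).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {CONTRASTS}")
    arr = np.asarray(local_wd, dtype=float)
    if arr.ndim != 4 or arr.shape[0] < 2:
        raise ValueError("need (subject, sleep, task, channel) with >= 2 subjects")
    task_minus_rest = arr[:, :, 1:, :].mean(axis=2) - arr[:, :, 0, :]
    if contrast == "task_minus_rest_before":
        x = task_minus_rest[:, 0, :]
    elif contrast == "task_minus_rest_after":
        x = task_minus_rest[:, 1, :]
    else:
        x = task_minus_rest[:, 1, :] - task_minus_rest[:, 0, :]
    n = x.shape[0]
    mean = x.mean(axis=0)
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 1)
    p = np.where((se == 0) & (mean == 0), 1.0, p)
    _, p_fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "channel": np.arange(x.shape[1]), "mean": mean, "t": t,
        "p_uncorrected": p, "p_fdr": p_fdr,
    })
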