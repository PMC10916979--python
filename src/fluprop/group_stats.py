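"""Group-level discrimination: mixed ANCOVA, Tukey HSD, effect sizes.

The design is a 2 x 2 mixed model: diagnostic group (between subjects, two
levels per comparison) by fluency task (within subjects, phonemic vs
semantic), with sex, age, and years of education as covariates entered as
additive fixed effects (no covariate x factor interactions), Type III sums
of squares, and partial eta squared per term.  Post-hoc pairwise cell
contrasts use Tukey's honestly significant difference with Cohen's d
(pooled-SD denominator) as the effect size.

With a two-level within factor the split-plot model decomposes exactly into
two ordinary ANCOVAs: the between-subject effects act on each subject's
task mean, and the task and group x task effects act on each subject's task
difference.  That decomposition is what :func:`mixed_ancova` computes;
continuous covariates are grand-mean centered and categorical ones
sum-to-zero coded, so the tests match the conventional Type III analysis of
the full long-format model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age", "education")


@dataclass(frozen=True)
class AncovaResult:
    """One model term of a mixed ANCOVA."""

    outcome: str
    term: str  # "group", "task", or "group:task"
    F: float
    df: tuple[int, int]
    p: float
    eta_p_sq: float
    mse: float  # error mean square of the term's stratum, long-data scale
    covariates: tuple[str, ...] = DEFAULT_COVARIATES


@dataclass(frozen=True)
class PosthocResult:
    """One Tukey-adjusted pairwise cell contrast."""

    contrast: str
    mean_diff: float
    p: float
    cohen_d: float


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """eta_p^2 = SS_effect / (SS_effect + SS_error)."""
    if ss_error <= 0:
        raise ValueError("zero or negative error sum of squares")
    return ss_effect / (ss_effect + ss_error)


def cohen_d(a, b) -> float:
    """Standardized mean difference with the pooled-SD denominator."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least two observations per sample")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _design(sub: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, dict[str, int]]:
    """Intercept + centered/sum-coded covariates + sum-coded group."""
    n = len(sub)
    cols = [np.ones(n)]
    names = {"intercept": 0}
    for cov in covariates:
        v = sub[cov]
        if v.dtype == object or str(v.dtype) == "category" or v.dtype == bool:
            levels = sorted(pd.unique(v.astype(str)))
            if len(levels) == 1:
                continue  # constant covariate carries no information
            if len(levels) != 2:
                raise ValueError(f"categorical covariate {cov!r} must have two levels")
            coded = np.where(v.astype(str) == levels[0], 1.0, -1.0)
        else:
            coded = v.to_numpy(dtype=float)
            coded = coded - coded.mean()
        names[cov] = len(cols)
        cols.append(coded)
    groups = sorted(pd.unique(sub["group"]))
    gcol = np.where(sub["group"] == groups[0], 1.0, -1.0)
    names["group"] = len(cols)
    cols.append(gcol)
    return np.column_stack(cols), names


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _type3_F(X: np.ndarray, y: np.ndarray, col: int) -> tuple[float, float, int, float]:
    """Drop-one-column Type III test: (F, SS_effect, df_den, SS_error)."""
    n, p = X.shape
    rss_full = _ols_rss(X, y)
    rss_red = _ols_rss(np.delete(X, col, axis=1), y)
    ss_eff = max(rss_red - rss_full, 0.0)
    df_den = n - p
    if df_den <= 0:
        raise ValueError("not enough subjects for the model")
    F = (ss_eff / 1.0) / (rss_full / df_den)
    return F, ss_eff, df_den, rss_full


def mixed_ancova(
    data: pd.DataFrame,
    outcome: str = "value",
    between: tuple[str, str] | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    tasks: tuple[str, str] = ("phonemic", "semantic"),
) -> list[AncovaResult]:
    """2 (group) x 2 (task) mixed ANCOVA on a long-format outcome.

    ``data`` has one row per participant x task with columns
    ``participant_id, group, task`` plus the outcome and covariates.
    ``between`` selects the two groups compared (default: the two present).
    Participants missing either task's value or any covariate are dropped
    listwise (logged).  Returns the group, task, and group x task terms.
    """
    df = data.copy()
    if between is not None:
        df = df[df["group"].isin(between)]
    groups = sorted(pd.unique(df["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")

    wide = df.pivot_table(index="participant_id", columns="task", values=outcome, aggfunc="first")
    missing_task = [t for t in tasks if t not in wide.columns]
    if missing_task:
        raise ValueError(f"no observations for task(s) {missing_task}")
    subj = df.drop_duplicates("participant_id").set_index("participant_id")
    sub = subj.join(wide[list(tasks)], how="inner")
    needed = list(tasks) + [c for c in covariates if c in sub.columns]
    absent = [c for c in covariates if c not in sub.columns]
    if absent:
        raise ValueError(f"covariates missing from data: {absent}")
    before = len(sub)
    sub = sub.dropna(subset=needed)
    dropped = before - len(sub)
    if dropped:
        logger.info("mixed_ancova(%s): listwise deletion removed %d participants", outcome, dropped)
    counts = sub["group"].value_counts()
    if counts.min() < 3 or len(counts) < 2:
        raise ValueError(f"fewer than 3 complete participants in a group: {counts.to_dict()}")

    y1 = sub[tasks[0]].to_numpy(dtype=float)
    y2 = sub[tasks[1]].to_numpy(dtype=float)
    if np.ptp(np.concatenate([y1, y2])) == 0:
        raise ValueError(f"outcome {outcome!r} is constant")

    X, names = _design(sub, covariates)
    used_covs = tuple(c for c in covariates if c in names)

    results: list[AncovaResult] = []
    # between stratum: subject task means; SS on means are half the
    # long-data between-subject SS (two observations per subject)
    m = (y1 + y2) / 2.0
    F_g, ss_g, dfd, rss_between = _type3_F(X, m, names["group"])
    results.append(
        AncovaResult(
            outcome=outcome,
            term="group",
            F=F_g,
            df=(1, dfd),
            p=float(stats.f.sf(F_g, 1, dfd)),
            eta_p_sq=partial_eta_squared(ss_g, rss_between),
            mse=2.0 * rss_between / dfd,
            covariates=used_covs,
        )
    )
    # within stratum: task differences; SS on differences are twice the
    # long-data within-subject SS.  Covariates enter additively (subject
    # level only, no covariate x task interaction), so they cancel from the
    # difference scores and the within model is intercept + group.
    d = y1 - y2
    gcol = X[:, names["group"]]
    Xw = np.column_stack([np.ones(len(d)), gcol])
    mse_within = None
    for term, col in (("task", 0), ("group:task", 1)):
        F_t, ss_t, dfd, rss_within = _type3_F(Xw, d, col)
        mse_within = rss_within / dfd / 2.0
        results.append(
            AncovaResult(
                outcome=outcome,
                term=term,
                F=F_t,
                df=(1, dfd),
                p=float(stats.f.sf(F_t, 1, dfd)),
                eta_p_sq=partial_eta_squared(ss_t, rss_within),
                mse=mse_within,
                covariates=used_covs,
            )
        )
    return results


def tukey_posthoc(
    data: pd.DataFrame,
    outcome: str = "value",
    between: tuple[str, str] | None = None,
) -> list[PosthocResult]:
    """All pairwise group x task cell contrasts, Tukey-HSD adjusted.

    Cell means are compared with the studentized-range distribution over the
    k = (groups x tasks) cells using the pooled within-cell variance
    (Tukey-Kramer standard errors for unequal cell sizes); Cohen's d uses
    the two cells' pooled SD.  Intended for significant interaction terms;
    enforcement of that policy is the caller's.
    """
    df = data.copy()
    if between is not None:
        df = df[df["group"].isin(between)]
    cells = {
        (g, t): sub[outcome].dropna().to_numpy(dtype=float)
        for (g, t), sub in df.groupby(["group", "task"])
    }
    if any(v.size < 2 for v in cells.values()):
        raise ValueError("each group x task cell needs at least 2 observations")
    k = len(cells)
    df_err = sum(v.size - 1 for v in cells.values())
    msw = sum((v.size - 1) * v.var(ddof=1) for v in cells.values()) / df_err
    if msw == 0:
        raise ValueError("zero within-cell variance; post-hocs undefined")
    out = []
    for (ka, va), (kb, vb) in itertools.combinations(cells.items(), 2):
        diff = va.mean() - vb.mean()
        se = np.sqrt(msw / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_err))
        out.append(
            PosthocResult(
                contrast=f"{ka[0]}:{ka[1]} - {kb[0]}:{kb[1]}",
                mean_diff=float(diff),
                p=min(max(p, 0.0), 1.0),
                cohen_d=cohen_d(va, vb),
            )
        )
    return out


def ancova_results_frame(results: list[AncovaResult]) -> pd.DataFrame:
    """Tidy table of ANCOVA terms (term, F, df1, df2, p, eta_p_sq, mse)."""
    return pd.DataFrame(
        {
            "outcome": [r.outcome for r in results],
            "term": [r.term for r in results],
            "F": [r.F for r in results],
            "df1": [r.df[0] for r in results],
            "df2": [r.df[1] for r in results],
            "p": [r.p for r in results],
            "eta_p_sq": [r.eta_p_sq for r in results],
            "mse": [r.mse for r in results],
        }
    )
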