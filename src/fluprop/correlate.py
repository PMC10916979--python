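"""Brain/behavior correlation batteries with FDR control.

Fluency-derived measures are correlated with cognitive outcomes (e.g., IFS
executive scores) or neural markers (network strengths, cluster-mean
connectivity), typically collapsing one patient group with healthy controls
to increase variance.  Each declared battery of tests is corrected together
with the Benjamini-Hochberg false-discovery-rate step-up procedure.  The
test statistic is Spearman's rho by policy, or chosen per pair by
Shapiro-Wilk normality of both variables (Pearson only when both pass at
alpha = 0.05).  Partial correlations remove a set of control covariates
from both variables by linear regression (after rank transformation for
the Spearman variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    method: str  # spearman | pearson | partial-spearman | partial-pearson
    rho: float
    p: float
    n: int
    p_fdr: float | None = None
    controls: tuple[str, ...] = ()


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _choose_method(x: np.ndarray, y: np.ndarray, policy: str, alpha: float = 0.05) -> str:
    if policy in ("spearman", "pearson"):
        return policy
    if policy != "auto":
        raise ValueError(f"method policy must be spearman/pearson/auto, got {policy!r}")
    # Pearson only when BOTH variables pass Shapiro-Wilk normality
    px = stats.shapiro(x).pvalue
    py = stats.shapiro(y).pvalue
    return "pearson" if (px > alpha and py > alpha) else "spearman"


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def correlation_battery(
    data: pd.DataFrame,
    measures: list[str],
    targets: list[str],
    groups: tuple[str, ...] | None = None,
    method_policy: str = "spearman",
    min_n: int = 4,
) -> list[CorrelationResult]:
    """Correlate every measure x target pair on a pooled sample, with FDR.

    ``groups`` restricts ``data`` (which must then carry a ``group`` column)
    to a patient-group + control pool before correlating.  Pairs with fewer
    than ``min_n`` complete observations are skipped with a log entry.  All
    computed pairs form one FDR battery: Benjamini-Hochberg adjusted
    p-values are filled into ``p_fdr``.
    """
    df = data
    if groups is not None:
        df = df[df["group"].isin(groups)]
    results: list[CorrelationResult] = []
    for m in measures:
        for t in targets:
            sub = df[[m, t]].dropna()
            if len(sub) < min_n:
                logger.warning("skipping %s ~ %s: only %d complete pairs", m, t, len(sub))
                continue
            x = sub[m].to_numpy(dtype=float)
            y = sub[t].to_numpy(dtype=float)
            method = _choose_method(x, y, method_policy)
            rho, p = _corr(x, y, method)
            results.append(CorrelationResult(x=m, y=t, method=method, rho=rho, p=p, n=len(sub)))
    if results:
        adj = bh_fdr([r.p for r in results])
        results = [
            CorrelationResult(
                x=r.x, y=r.y, method=r.method, rho=r.rho, p=r.p, n=r.n, p_fdr=float(a)
            )
            for r, a in zip(results, adj)
        ]
    return results


def partial_correlation(
    x,
    y,
    controls,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation of x and y after linear removal of control covariates.

    ``controls`` is an (n, k) array or DataFrame, complete for every
    observation used.  For the Spearman variant all variables are rank
    transformed before residualization.  Collinear controls or a variable
    fully explained by the controls raise an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(controls, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if not (len(x) == len(y) == len(C)):
        raise ValueError("x, y, and controls must have equal length")
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(C).any():
        raise ValueError("partial_correlation requires complete data")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        C = np.apply_along_axis(stats.rankdata, 0, C)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    Z = np.column_stack([np.ones(len(x)), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear controls")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the controls")
    r = stats.pearsonr(rx, ry)
    # degrees of freedom lose one per control: recompute p on n - 2 - k
    n, k = len(x), C.shape[1]
    dof = n - 2 - k
    if dof <= 0:
        raise ValueError("not enough observations for the number of controls")
    rho = float(r.statistic)
    t = rho * np.sqrt(dof / max(1e-300, 1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return CorrelationResult(
        x="x",
        y="y",
        method=f"partial-{method}",
        rho=rho,
        p=min(p, 1.0),
        n=n,
        controls=tuple(f"c{i}" for i in range(k)),
    )


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy table of correlation results."""
    return pd.DataFrame(
        {
            "x": [r.x for r in results],
            "y": [r.y for r in results],
            "method": [r.method for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "n": [r.n for r in results],
        }
    )
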