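"""Spearman screening of speech features against UCLA Loneliness scores.

Every feature is tested at alpha = 0.05 without multiplicity adjustment,
mirroring the exploratory protocol; a Benjamini-Hochberg option exists but
is off by default.  Confound control for age and sex is rank-based partial
correlation: ranks of feature and score are residualized on the confounders
by least squares and the residuals correlated.  A Fisher-z post-hoc power
computation is included for sample-size reasoning at the observed effect
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    feature_name: str
    rho: float
    p_value: float
    significant: bool
    adjusted_rho: float | None = None
    adjusted_p: float | None = None

    @property
    def sign(self) -> int:
        return int(np.sign(self.rho))


def spearman_rho(x, y):
    """Spearman rank correlation with two-sided p from the t approximation.

    rho is the Pearson correlation of mid-ranks; p comes from
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need n >= 4")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def spearman_exact_p(x, y):
    """Exact permutation p for tiny n (<= 10); reference mode for audits."""
    from itertools import permutations

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size > 10:
        raise ValueError("exact mode is limited to n <= 10")
    rho_obs, _ = spearman_rho(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        count += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    return rho_obs, count / total


def partial_spearman(x, y, confounders):
    """Rank-based partial correlation of x and y given confounder columns.

    All variables (including confounders) are rank-transformed, x and y are
    residualized on an intercept plus the confounder ranks by least squares,
    and the residuals correlated; the p-value uses a t test on n - 2 - k df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(confounders, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    n, k = Z.shape
    if n <= k + 2:
        raise ValueError("need n > #confounders + 2")
    Z = np.column_stack([stats.rankdata(Z[:, j]) for j in range(k)])
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear confounders")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    # a variable explained (near-)exactly by the confounders leaves only
    # numerical noise; report zero partial correlation rather than junk
    if ((res_x**2).sum() < 1e-8 * ((rx - rx.mean()) ** 2).sum()
            or (res_y**2).sum() < 1e-8 * ((ry - ry.mean()) ** 2).sum()):
        return 0.0, 1.0
    denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
    rho = float((res_x * res_y).sum() / denom)
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return rho, p


def screen_features(
    table: pd.DataFrame,
    scores,
    alpha: float = 0.05,
    confounders: pd.DataFrame | None = None,
    bh_adjust: bool = False,
) -> list:
    """Spearman-screen every feature column against the score vector.

    Returns CorrelationResults for all columns, flagged at p < alpha
    (Benjamini-Hochberg across features only if ``bh_adjust``), sorted by
    |rho| descending with name as tie-break.  Constant columns are reported
    with rho = 0, p = 1 rather than aborting the screen.
    """
    scores = np.asarray(scores, dtype=float)
    results = []
    pvals = {}
    for name in table.columns:
        col = table[name].to_numpy(dtype=float)
        ok = np.isfinite(col)
        try:
            rho, p = spearman_rho(col[ok], scores[ok])
        except ValueError:
            rho, p = 0.0, 1.0
        adj_rho = adj_p = None
        if confounders is not None:
            try:
                adj_rho, adj_p = partial_spearman(
                    col[ok], scores[ok], confounders.loc[ok].to_numpy(dtype=float)
                )
            except ValueError:
                adj_rho, adj_p = 0.0, 1.0
        pvals[name] = p
        results.append((name, rho, p, adj_rho, adj_p))

    if bh_adjust:
        names = list(pvals)
        rej = _benjamini_hochberg(np.array([pvals[n] for n in names]), alpha)
        flagged = {n for n, r in zip(names, rej) if r}
    else:
        flagged = {n for n, p in pvals.items() if p < alpha}

    out = [
        CorrelationResult(n, rho, p, n in flagged, adj_rho, adj_p)
        for n, rho, p, adj_rho, adj_p in results
    ]
    out.sort(key=lambda r: (-abs(r.rho), r.feature_name))
    return out


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    rej = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.nonzero(passed)[0])
        rej[order[: kmax + 1]] = True
    return rej


def screen_report(results) -> pd.DataFrame:
    """Tabular screening report (feature, rho, p, significance, adjusted)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature_name,
                "rho": r.rho,
                "p": r.p_value,
                "significant": r.significant,
                "adjusted_rho": r.adjusted_rho,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )


def posthoc_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided Spearman test at assumed effect rho, via the
    Fisher-z normal approximation: Phi(|atanh rho| * sqrt(n-3) - z_{1-a/2})."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(np.arctanh(rho)) * np.sqrt(n - 3) - z_crit))
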