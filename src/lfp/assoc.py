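"""Score-clinical association statistics.

Test choice follows feature arity: three or more groups use the
Kruskal-Wallis rank test, two groups the two-sided Wilcoxon rank-sum
test (exact for small tie-free samples, normal approximation with
continuity correction otherwise), and continuous cell-count covariates
use Pearson correlation between the score and the log10-transformed
count (scores may be negative and enter untransformed). The
neutrophil-to-lymphocyte ratio is neutrophils / (B + T cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "pearson_log",
    "PearsonLogResult",
    "nlr",
    "association_table",
]


def _grouped(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    uniq = pd.unique(groups)
    parts = [values[groups == g] for g in uniq]
    if any(len(p) == 0 for p in parts):
        raise ValueError("every group must be nonempty")
    return parts


def kruskal_wallis(values, groups):
    """Tie-corrected Kruskal-Wallis H with a chi-square p (g-1 df).

    All-equal values make the tie correction degenerate; H is defined
    as 0 there (p = 1).
    """
    parts = _grouped(values, groups)
    if len(parts) < 3:
        raise ValueError("need >= 3 groups; use wilcoxon_rank_sum for 2")
    flat = np.concatenate(parts)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*parts)
    return float(h), float(p)


def wilcoxon_rank_sum(values, groups):
    """Two-sided Wilcoxon rank-sum test for exactly two groups.

    Returns ``(W, p)`` with W the rank sum of the first group. The p is
    exact when both groups are small (min n <= 20) and tie-free,
    otherwise the tie/continuity-corrected normal approximation.
    """
    parts = _grouped(values, groups)
    if len(parts) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(parts)}")
    x, y = parts
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic + len(x) * (len(x) + 1) / 2)  # U -> rank sum
    return w, float(res.pvalue)


@dataclass
class PearsonLogResult:
    r: float
    p: float
    n: int
    slope: float
    intercept: float
    x: np.ndarray  # score values used
    log_y: np.ndarray  # log10 counts used

    def conf_band(self, x_grid) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise 95% CI of the fitted mean line at ``x_grid``."""
        x_grid = np.asarray(x_grid, dtype=float)
        n = self.n
        resid = self.log_y - (self.intercept + self.slope * self.x)
        s2 = (resid**2).sum() / (n - 2)
        xbar = self.x.mean()
        sxx = ((self.x - xbar) ** 2).sum()
        se = np.sqrt(s2 * (1.0 / n + (x_grid - xbar) ** 2 / sxx))
        tcrit = scipy.stats.t.ppf(0.975, n - 2)
        mid = self.intercept + self.slope * x_grid
        return mid - tcrit * se, mid + tcrit * se


def pearson_log(scores, counts) -> PearsonLogResult:
    """Pearson correlation of a score against log10-transformed counts,
    with a linear fit for plotting. Missing pairs are dropped; counts
    must be strictly positive."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(counts, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.any(y <= 0):
        raise ValueError("counts must be > 0 for the log transform")
    ly = np.log10(y)
    if x.std() == 0 or ly.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = scipy.stats.pearsonr(x, ly)
    slope, intercept = np.polyfit(x, ly, 1)
    return PearsonLogResult(r=float(r), p=float(p), n=len(x),
                            slope=float(slope), intercept=float(intercept),
                            x=x, log_y=ly)


def nlr(neutrophils, b_cells, t_cells):
    """Neutrophil-to-lymphocyte ratio: neutrophils / (B + T). A zero
    lymphocyte total is undefined and recorded as missing (NaN)."""
    n = np.asarray(neutrophils, dtype=float)
    lym = np.asarray(b_cells, dtype=float) + np.asarray(t_cells, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(lym > 0, n / np.where(lym > 0, lym, 1.0), np.nan)
    return out if out.ndim else float(out)


def association_table(scores: pd.DataFrame, meta: pd.DataFrame,
                      features) -> pd.DataFrame:
    """One test per (score, feature) pair, chosen by feature arity.

    Categorical features with >= 3 levels get Kruskal-Wallis, with 2
    levels the Wilcoxon rank-sum; numeric features get Pearson on the
    log10-transformed feature. Returns rows of
    (score_name, feature, test, statistic, p, n).
    """
    rows = []
    common = scores.index.intersection(meta.index)
    for feat in features:
        fvals = meta.loc[common, feat]
        categorical = (
            fvals.dtype == object
            or isinstance(fvals.dtype, pd.CategoricalDtype)
            or fvals.nunique() <= max(3, int(np.sqrt(len(fvals))) // 2)
        )
        for score_name in scores.columns:
            svals = scores.loc[common, score_name]
            ok = svals.notna() & fvals.notna()
            s, f = svals[ok], fvals[ok]
            if categorical:
                n_groups = f.nunique()
                if n_groups >= 3:
                    stat, p = kruskal_wallis(s.to_numpy(), f.to_numpy())
                    test = "kruskal-wallis"
                elif n_groups == 2:
                    stat, p = wilcoxon_rank_sum(s.to_numpy(), f.to_numpy())
                    test = "wilcoxon"
                else:
                    continue
            else:
                res = pearson_log(s.to_numpy(), f.to_numpy())
                stat, p, test = res.r, res.p, "pearson-log"
            rows.append(
                {"score": score_name, "feature": feat, "test": test,
                 "statistic": stat, "p": p, "n": int(ok.sum())}
            )
    return pd.DataFrame(rows)
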