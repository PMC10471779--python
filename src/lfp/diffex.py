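"""Per-gene linear-model differential expression and reversal analysis.

Each gene's normalized expression is regressed on a two-group indicator
(plus optional covariates) by ordinary least squares; the group
coefficient is the log2-scale effect and its two-sided t-test gives the
p-value. P-values are Benjamini-Hochberg adjusted, effects are
exponentiated to a signed linear fold-change (|FC| >= 1 by convention),
and a gene is called UP/DOWN when q <= fdr_max and |FC| >= fc_min
(inclusive thresholds).

The treatment-reversal analysis first calls pathology genes from the
disease-vs-control contrast, then, per treated arm, counts a pathology
gene as reversed when its treated-vs-disease change is significant in
the direction opposite to the disease change ("opposite_significant",
default), or when the treated arm is no longer distinguishable from
control on that gene ("restored").
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ReversalReport

__all__ = [
    "fit_gene_models",
    "fold_change",
    "bh_adjust",
    "call_de",
    "de_analysis",
    "overlap_sets",
    "reversal_analysis",
]

P_FLOOR = 1e-300  # clamp for zero-residual fits

DEFAULT_FC_MIN = 1.3
DEFAULT_FDR_MAX = 0.05


def _design(group: pd.Series, contrast, covariates: pd.DataFrame | None):
    g1, g2 = contrast
    samples = group.index[group.isin([g1, g2])]
    if (group.loc[samples] == g1).sum() < 2 or (group.loc[samples] == g2).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    indicator = (group.loc[samples] == g2).astype(float).to_numpy()
    cols = [np.ones(len(samples)), indicator]
    names = ["intercept", f"{g2}_vs_{g1}"]
    if covariates is not None:
        cov = covariates.loc[samples]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        _, R = np.linalg.qr(D)
        bad = [names[i] for i in range(D.shape[1]) if abs(R[i, i]) < 1e-10]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return samples, D, names


def fit_gene_models(X_norm: ExpressionMatrix, group: pd.Series, contrast,
                    covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """OLS of each gene's normalized expression on a group indicator.

    ``contrast=(g1, g2)`` makes the effect the g2-minus-g1 difference
    (adjusted for covariates); p is the two-sided t-test on that
    coefficient with residual degrees of freedom. Zero-residual fits get
    p = 1 for a zero effect and the floor ``P_FLOOR`` otherwise.
    """
    samples, D, _ = _design(group, contrast, covariates)
    Y = X_norm.data[list(samples)].to_numpy(dtype=float).T  # n x genes
    n, p = D.shape
    dof = n - p
    if dof < 1:
        raise ValueError("not enough residual degrees of freedom")
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ (D.T @ Y)
    resid = Y - D @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * DtD_inv[1, 1])
    effect = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    zero_resid = se == 0
    pvals = np.where(zero_resid & (effect == 0), 1.0, pvals)
    pvals = np.where(zero_resid & (effect != 0), P_FLOOR, pvals)
    pvals = np.maximum(pvals, P_FLOOR)
    return pd.DataFrame(
        {"effect": effect, "p": pvals}, index=X_norm.gene_ids
    ).rename_axis("gene_id")


def fold_change(effect):
    """Signed linear fold-change of a log2-scale effect: 2**effect when
    >= 1, else -1/2**effect, so |fc| >= 1 always."""
    r = np.exp2(np.asarray(effect, dtype=float))
    fc = np.where(r >= 1.0, r, -1.0 / r)
    return fc if fc.ndim else float(fc)


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, fc_min: float = DEFAULT_FC_MIN,
            fdr_max: float = DEFAULT_FDR_MAX) -> pd.DataFrame:
    """Add UP/DOWN/NS calls with inclusive thresholds."""
    out = results.copy()
    sig = out["q"] <= fdr_max
    out["call"] = "NS"
    out.loc[sig & (out["fc"] >= fc_min), "call"] = "UP"
    out.loc[sig & (out["fc"] <= -fc_min), "call"] = "DOWN"
    return out


def de_analysis(X_norm: ExpressionMatrix, group: pd.Series, contrast,
                covariates: pd.DataFrame | None = None,
                fc_min: float = DEFAULT_FC_MIN,
                fdr_max: float = DEFAULT_FDR_MAX) -> pd.DataFrame:
    """Full per-gene DE table: effect, fc, p, q, call."""
    res = fit_gene_models(X_norm, group, contrast, covariates)
    res["fc"] = fold_change(res["effect"].to_numpy())
    res["q"] = bh_adjust(res["p"].to_numpy())
    return call_de(res, fc_min=fc_min, fdr_max=fdr_max)


def overlap_sets(call_sets: dict) -> dict[frozenset, set]:
    """Inclusion-exclusion partition of DE genes across groups.

    ``call_sets`` maps group name -> set of DE genes; the result maps
    each nonempty group combination to the genes DE in exactly those
    groups. Partition sizes sum to the union size.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least 2 call sets")
    names = list(call_sets)
    partition: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(call_sets[n]) for n in combo))
            outside = set.union(
                set(), *(set(call_sets[n]) for n in names if n not in combo)
            )
            cell = inside - outside
            if cell:
                partition[frozenset(combo)] = cell
    return partition


def reversal_analysis(X_norm: ExpressionMatrix, arms: pd.Series,
                      control: str = "control", disease: str = "disease",
                      treatments=None, fc_min: float = DEFAULT_FC_MIN,
                      fdr_max: float = DEFAULT_FDR_MAX,
                      rule: str = "opposite_significant") -> ReversalReport:
    """Pathology DEGs (disease vs control) and their per-arm reversal."""
    present = set(arms.unique())
    for a in (control, disease):
        if a not in present:
            raise ValueError(f"arm {a!r} missing from the annotation")
    if rule not in ("opposite_significant", "restored"):
        raise ValueError(f"unknown reversal rule {rule!r}")
    if treatments is None:
        treatments = [a for a in arms.unique() if a not in (control, disease)]

    patho = de_analysis(X_norm, arms, (control, disease),
                        fc_min=fc_min, fdr_max=fdr_max)
    up = patho.index[patho["call"] == "UP"].tolist()
    down = patho.index[patho["call"] == "DOWN"].tolist()
    patho_sign = pd.concat(
        [pd.Series(1, index=up), pd.Series(-1, index=down)]
    )

    reversed_by_arm: dict[str, list[str]] = {}
    for arm in treatments:
        if rule == "opposite_significant":
            de = de_analysis(X_norm, arms, (disease, arm),
                             fc_min=fc_min, fdr_max=fdr_max)
            calls = de.loc[patho_sign.index, "call"]
            opposite = patho_sign.map({1: "DOWN", -1: "UP"})
            rev = patho_sign.index[calls == opposite]
        else:
            de = de_analysis(X_norm, arms, (control, arm),
                             fc_min=fc_min, fdr_max=fdr_max)
            rev = patho_sign.index[de.loc[patho_sign.index, "call"] == "NS"]
        reversed_by_arm[arm] = rev.tolist()

    return ReversalReport(
        pathology_up=up, pathology_down=down, reversed_by_arm=reversed_by_arm
    )
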