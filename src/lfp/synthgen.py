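"""Synthetic cohort and preclinical-study generators with ground truth.

The generators emulate the statistical structure the downstream stages
assume, not any particular real dataset:

* ``gen_cohort`` — a healthy-volunteer (HV) population plus three patient
  clusters carrying a severity gradient (C3 > C1 > C2 ~ HV) planted on a
  fingerprint gene set (48 up / 21 down by default) embedded in a larger
  candidate panel (248 genes by default). Counts are negative binomial
  with sample-specific library sizes; clinical covariates (neutrophil,
  B-cell and T-cell counts) are drawn log-normally with neutrophils
  increasing and lymphocytes decreasing along the severity gradient.
* ``gen_preclinical`` — a five-arm design (control, disease, three
  treatments) with planted disease DEGs (484 up / 26 down by default) of
  which a per-arm fraction is reverted to the control mean.

Everything is reproducible from the config seed, and every planted
feature is recorded in a :class:`SyntheticTruth` for recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigError, ExpressionMatrix

__all__ = [
    "CohortConfig",
    "PreclinicalConfig",
    "SyntheticTruth",
    "gen_cohort",
    "gen_preclinical",
    "write_dataset",
]

# Baseline expression: log-normal so the low-expression filter has work
# to do; signature/DEG genes floored at a clearly-detected level, the way
# curated panels are restricted to reliably expressed transcripts.
_BASE_MEANLOG = 4.0
_BASE_SDLOG = 1.5
_SIGNAL_FLOOR = 20.0

# Clinical covariates on log10 scale: baseline cells/uL and per-severity-
# unit slopes (neutrophilia, B/T lymphopenia along the gradient).
_CLINICAL_MODEL = {
    "neutrophils": {"base": 3.60, "coef": 0.15, "sd": 0.12},
    "b_cells": {"base": 2.30, "coef": -0.15, "sd": 0.12},
    "t_cells": {"base": 3.05, "coef": -0.10, "sd": 0.12},
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic patient cohort."""

    n_hv: int = 100
    n_per_cluster: dict[str, int] = field(
        default_factory=lambda: {"C1": 86, "C2": 120, "C3": 43}
    )
    n_genes: int = 10000
    n_fingerprint_up: int = 48
    n_fingerprint_down: int = 21
    n_candidates: int = 248
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"C1": 0.5, "C2": 0.0, "C3": 1.0}
    )
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.4)
    batch_effects: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hv < 1 or any(n < 1 for n in self.n_per_cluster.values()):
            raise ConfigError("all sample counts must be >= 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        n_fp = self.n_fingerprint_up + self.n_fingerprint_down
        if not (0 < n_fp <= self.n_candidates <= self.n_genes):
            raise ConfigError(
                "need fingerprint size <= n_candidates <= n_genes"
            )
        if np.isscalar(self.dispersion) and self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ConfigError("libsize_range must be a positive interval")
        if set(self.effect_sizes) != set(self.n_per_cluster):
            raise ConfigError("effect_sizes keys must match cluster names")
        if set(self.n_per_cluster) == {"C1", "C2", "C3"}:
            e = self.effect_sizes
            if not (e["C3"] >= e["C1"] >= e["C2"]):
                raise ConfigError("gradient preset requires C3 >= C1 >= C2")


@dataclass
class PreclinicalConfig:
    """Parameters of the synthetic multi-arm preclinical design."""

    arms: dict[str, int] = field(
        default_factory=lambda: {
            "control": 11,
            "disease": 12,
            "treatment_A": 12,
            "treatment_B": 12,
            "treatment_C": 12,
        }
    )
    control_arm: str = "control"
    disease_arm: str = "disease"
    n_genes: int = 10000
    n_degs_up: int = 484
    n_degs_down: int = 26
    deg_effect: float = 1.5
    reversal_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "treatment_A": 0.87,
            "treatment_B": 0.60,
            "treatment_C": 0.35,
        }
    )
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    @property
    def n_disease_degs(self) -> int:
        return self.n_degs_up + self.n_degs_down

    @property
    def treatment_arms(self) -> list[str]:
        return [
            a
            for a in self.arms
            if a not in (self.control_arm, self.disease_arm)
        ]

    def __post_init__(self) -> None:
        if self.control_arm not in self.arms or self.disease_arm not in self.arms:
            raise ConfigError("arms must contain exactly one control and one disease arm")
        if self.control_arm == self.disease_arm:
            raise ConfigError("control and disease arms must differ")
        if any(n < 1 for n in self.arms.values()):
            raise ConfigError("all arm sizes must be >= 1")
        if not (0 < self.n_disease_degs <= self.n_genes):
            raise ConfigError("need 0 < n_disease_degs <= n_genes")
        for arm, f in self.reversal_fraction.items():
            if arm not in self.treatment_arms:
                raise ConfigError(f"reversal fraction given for unknown arm {arm!r}")
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"reversal_fraction must lie in [0, 1], got {f}")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator."""

    true_cluster: dict[str, str]  # sample_id -> cluster / HV / arm
    fingerprint_up: list[str] = field(default_factory=list)
    fingerprint_down: list[str] = field(default_factory=list)
    candidate_genes: list[str] = field(default_factory=list)
    degs_up: list[str] = field(default_factory=list)
    degs_down: list[str] = field(default_factory=list)
    reversed_by_arm: dict[str, list[str]] = field(default_factory=dict)
    clinical_coefficients: dict[str, float] = field(default_factory=dict)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        genes = set(matrix.gene_ids)
        planted = (
            set(self.fingerprint_up)
            | set(self.fingerprint_down)
            | set(self.candidate_genes)
            | set(self.degs_up)
            | set(self.degs_down)
        )
        if not planted <= genes:
            raise ValueError("truth references genes absent from the matrix")
        degs = set(self.degs_up) | set(self.degs_down)
        for arm, rev in self.reversed_by_arm.items():
            if not set(rev) <= degs:
                raise ValueError(f"arm {arm!r}: reversed genes not all planted DEGs")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    alpha = np.asarray(alpha, dtype=float)
    r = 1.0 / alpha
    if r.ndim == 1:  # per-gene dispersion broadcast over samples
        r = r[:, None]
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def _base_expression(rng: np.random.Generator, n_genes: int, n_floored: int) -> np.ndarray:
    base = rng.lognormal(mean=_BASE_MEANLOG, sigma=_BASE_SDLOG, size=n_genes)
    base[:n_floored] = np.maximum(base[:n_floored], _SIGNAL_FLOOR)
    return base


def _libsizes(rng: np.random.Generator, n: int, rng_interval) -> np.ndarray:
    lo, hi = rng_interval
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def gen_cohort(config: CohortConfig):
    """Generate (ExpressionMatrix, annotation, SyntheticTruth) for a cohort.

    Counts for gene g, sample s are NB with mean
    ``libsize_s * base_g * 2**(signed effect)`` where the effect applies
    only to planted fingerprint genes in patient clusters (positive on
    up-genes, negative on down-genes, scaled by the cluster's severity).
    """
    rng = np.random.default_rng(config.seed)
    clusters = list(config.n_per_cluster)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    n_up, n_down = config.n_fingerprint_up, config.n_fingerprint_down
    fp_up = gene_ids[:n_up]
    fp_down = gene_ids[n_up : n_up + n_down]
    candidates = gene_ids[: config.n_candidates]

    sample_ids, roles, labels = [], [], []
    for i in range(config.n_hv):
        sample_ids.append(f"HV{i:04d}")
        roles.append("HV")
        labels.append("HV")
    for c in clusters:
        for i in range(config.n_per_cluster[c]):
            sample_ids.append(f"P{c}_{i:04d}")
            roles.append("patient")
            labels.append(c)
    n_samples = len(sample_ids)

    base = _base_expression(rng, config.n_genes, config.n_candidates)
    lib = _libsizes(rng, n_samples, config.libsize_range)

    # signed log2 effect per gene x sample
    log2_eff = np.zeros((config.n_genes, n_samples))
    sign = np.zeros(config.n_genes)
    sign[:n_up] = 1.0
    sign[n_up : n_up + n_down] = -1.0
    severity = np.array(
        [0.0 if l == "HV" else config.effect_sizes[l] for l in labels]
    )
    log2_eff = sign[:, None] * severity[None, :]

    batch = np.array(["B1"] * n_samples, dtype=object)
    if config.batch_effects:
        names = list(config.batch_effects)
        batch = np.array(names, dtype=object)[rng.integers(0, len(names), n_samples)]
        offsets = np.array([config.batch_effects[b] for b in batch])
        log2_eff = log2_eff + offsets[None, :]

    mu = lib[None, :] * base[:, None] * np.exp2(log2_eff)
    counts = _nb_draw(rng, mu, config.dispersion)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), layer="counts"
    )

    rin = rng.uniform(6.5, 10.0, size=n_samples)
    clinical = {}
    coefs = {}
    for name, m in _CLINICAL_MODEL.items():
        log10_val = m["base"] + m["coef"] * severity + rng.normal(
            0.0, m["sd"], size=n_samples
        )
        clinical[name] = np.power(10.0, log10_val)
        coefs[name] = m["coef"]

    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "role": roles,
            "cluster": labels,
            "rin": np.round(rin, 2),
            "batch": batch,
            **{k: np.round(v, 1) for k, v in clinical.items()},
        }
    ).set_index("sample_id")

    truth = SyntheticTruth(
        true_cluster=dict(zip(sample_ids, labels)),
        fingerprint_up=fp_up,
        fingerprint_down=fp_down,
        candidate_genes=candidates,
        clinical_coefficients=coefs,
    )
    truth.validate_against(matrix)
    return matrix, annotation, truth


def gen_preclinical(config: PreclinicalConfig):
    """Generate (ExpressionMatrix, annotation, SyntheticTruth) for a
    control / disease / treatment design with planted, partially
    reversible disease DEGs.

    The disease arm shifts planted DEGs by ``deg_effect`` log2 units
    (positive for up-genes, negative for down-genes). Each treatment arm
    restores the control mean on its reversed DEG subset and keeps the
    disease mean elsewhere; a reversal fraction of 1 makes the treated
    arm distributionally identical to control on the DEGs, and 0 makes
    it identical to disease.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    n_deg = config.n_disease_degs
    degs_up = gene_ids[: config.n_degs_up]
    degs_down = gene_ids[config.n_degs_up : n_deg]
    deg_idx = np.arange(n_deg)

    sample_ids, arms_col = [], []
    for arm, n in config.arms.items():
        for i in range(n):
            sample_ids.append(f"{arm}_{i:03d}")
            arms_col.append(arm)
    n_samples = len(sample_ids)
    arm_of = np.array(arms_col, dtype=object)

    base = _base_expression(rng, config.n_genes, n_deg)
    lib = _libsizes(rng, n_samples, config.libsize_range)

    sign = np.zeros(config.n_genes)
    sign[: config.n_degs_up] = 1.0
    sign[config.n_degs_up : n_deg] = -1.0

    reversed_by_arm: dict[str, list[str]] = {}
    # per-gene x sample log2 shift: disease-level everywhere except control
    # and each arm's reversed subset
    log2_eff = np.zeros((config.n_genes, n_samples))
    for arm in config.arms:
        cols = np.nonzero(arm_of == arm)[0]
        if arm == config.control_arm:
            continue
        shifted = sign.copy()
        if arm in config.treatment_arms:
            frac = config.reversal_fraction.get(arm, 0.0)
            n_rev = int(round(frac * n_deg))
            rev = np.sort(rng.choice(deg_idx, size=n_rev, replace=False))
            shifted[rev] = 0.0
            reversed_by_arm[arm] = [gene_ids[i] for i in rev]
        log2_eff[:, cols] = (config.deg_effect * shifted)[:, None]

    mu = lib[None, :] * base[:, None] * np.exp2(log2_eff)
    counts = _nb_draw(rng, mu, config.dispersion)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids), layer="counts"
    )
    annotation = pd.DataFrame(
        {"sample_id": sample_ids, "role": arms_col, "arm": arms_col}
    ).set_index("sample_id")

    truth = SyntheticTruth(
        true_cluster=dict(zip(sample_ids, arms_col)),
        degs_up=degs_up,
        degs_down=degs_down,
        reversed_by_arm=reversed_by_arm,
    )
    truth.validate_against(matrix)
    return matrix, annotation, truth


def write_dataset(outdir, matrix: ExpressionMatrix, annotation: pd.DataFrame,
                  truth: SyntheticTruth) -> None:
    """Write counts TSV, metadata TSV and truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    annotation.to_csv(outdir / "meta.tsv", sep="\t")
    (outdir / "truth.json").write_text(truth.to_json())
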