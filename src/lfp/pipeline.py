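"""End-to-end pipeline: preprocess -> cluster -> fingerprint -> score ->
differential expression / reversal -> associations -> PLS-DA.

A single global seed is split deterministically per stage (stable hash of
the stage name) so any stage can be rerun in isolation, and a rerun with
the same config and seed reproduces every output bit-identically. Each
output table carries a header comment with the parameter hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, diffex, exprprep, fingerprint, plsda, synthgen
from .containers import AMBIGUOUS, ConfigError, ExpressionMatrix
from .subtyping import ConsensusClusterer

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("lfp")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Validated parameters for the full pipeline run."""

    seed: int = 0
    simulate: bool = False
    counts: str | None = None
    meta: str | None = None
    candidates: str | None = None
    keep_list: str | None = None
    k: int | str = "auto"
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    n_top_genes: int = 150
    train_frac: float = 0.8
    tau: float = 0.6
    B: int = 200
    frequency_threshold: float = 1.0
    fc_min: float = 1.3
    fdr_max: float = 0.05
    ref_cluster: str | None = None
    cohort: dict = field(default_factory=dict)
    preclinical: dict | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ConfigError(f"fdr_max must lie in (0, 1], got {self.fdr_max}")
        if self.fc_min < 1:
            raise ConfigError(f"fc_min must be >= 1, got {self.fc_min}")
        if not (0 <= self.tau <= 1):
            raise ConfigError(f"tau must lie in [0, 1], got {self.tau}")
        if not (0 < self.frequency_threshold <= 1):
            raise ConfigError("frequency_threshold must lie in (0, 1]")
        if self.B < 1:
            raise ConfigError("B must be >= 1")
        if not (0 < self.train_frac <= 1):
            raise ConfigError("train_frac must lie in (0, 1]")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ConfigError("k must be 'auto' or an integer >= 2")
        if not self.simulate and (self.counts is None or self.meta is None):
            raise ConfigError("provide counts and meta paths, or set simulate")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)

    def params_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, phash: str, seed: int,
                index: bool = True, index_label=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# lfp v{__version__} params={phash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def _auto_ref_cluster(X_norm: ExpressionMatrix, labels: pd.Series,
                      panel_genes, hv_ids) -> str:
    """Most severe cluster = largest mean absolute deviation from the HV
    mean over the panel genes."""
    sub = X_norm.data.loc[list(panel_genes)]
    hv_mean = sub[list(hv_ids)].mean(axis=1)
    best, best_dev = None, -np.inf
    for c in sorted(labels.unique()):
        ids = labels.index[labels == c]
        dev = float((sub[list(ids)].mean(axis=1) - hv_mean).abs().mean())
        if dev > best_dev:
            best, best_dev = c, dev
    return best


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phash = config.params_hash()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params_hash": phash,
        "stages": [],
    }

    def done(stage: str, t0: float, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        log.info("stage=%s elapsed=%.1fs %s", stage, time.time() - t0, info)

    # ---- inputs ------------------------------------------------------
    t0 = time.time()
    truth = None
    if config.simulate:
        cc = synthgen.CohortConfig(
            **{**config.cohort, "seed": stage_seed(config.seed, "simulate")}
        )
        counts, meta, truth = synthgen.gen_cohort(cc)
        synthgen.write_dataset(outdir / "inputs", counts, meta, truth)
        candidate_genes = truth.candidate_genes
    else:
        counts = exprprep.read_counts(config.counts)
        meta = exprprep.read_annotation(config.meta)
        candidate_genes = None
        if config.candidates:
            candidate_genes = (
                pd.read_csv(config.candidates, sep="\t")
                .iloc[:, 0].astype(str).tolist()
            )
    done("inputs", t0, n_genes=counts.n_genes, n_samples=counts.n_samples)

    # ---- preprocess --------------------------------------------------
    t0 = time.time()
    keep = None
    if config.keep_list:
        keep = pd.read_csv(config.keep_list, sep="\t").iloc[:, 0].astype(str).tolist()
    norm, factors = exprprep.normalize(counts)
    norm, report = exprprep.filter_genes(norm, keep_list=keep)
    if "rin" in meta.columns and meta["rin"].notna().all():
        rin_class = meta.loc[list(norm.sample_ids), "rin"].map(exprprep.bin_rin)
        norm = exprprep.batch_center(norm, rin_class.to_numpy())
        meta = meta.assign(rin_class=meta["rin"].map(exprprep.bin_rin))
    write_table(norm.data, outdir / "normalized.tsv", phash, config.seed,
                index_label="gene_id")
    done("preprocess", t0, n_retained=report.n_retained,
         n_removed=report.n_input - report.n_retained)

    # ---- cluster -----------------------------------------------------
    t0 = time.time()
    patients = meta.index[meta["role"] != "HV"]
    hv_ids = meta.index[meta["role"] == "HV"].tolist()
    Xp = norm.data[list(patients)].T  # samples x genes
    rng = np.random.default_rng(stage_seed(config.seed, "split"))
    perm = rng.permutation(len(patients))
    n_train = max(int(round(config.train_frac * len(patients))), 3)
    train_ids = patients[np.sort(perm[:n_train])]
    test_ids = patients[np.sort(perm[n_train:])]

    clusterer = ConsensusClusterer(
        n_clusters=config.k, k_range=config.k_range,
        n_top_genes=config.n_top_genes, tau=config.tau,
        random_state=stage_seed(config.seed, "cluster"),
    ).fit(Xp.loc[train_ids])
    labels = pd.Series(clusterer.labels_, index=train_ids)
    assign = clusterer.labels_by_method_.copy()
    assign["consensus"] = labels
    assign["confidence"] = 1.0
    assign["retained"] = labels != AMBIGUOUS
    if len(test_ids):
        ext = clusterer.extend(Xp.loc[test_ids])
        ext_t = ext.table.copy()
        for m in ("hclust", "kmeans", "gmm"):
            ext_t[m] = np.nan
        ext_t = ext_t.rename(columns={"label": "consensus"})
        ext_t.loc[~ext_t["retained"], "consensus"] = AMBIGUOUS
        assign = pd.concat([assign, ext_t[assign.columns]])
    cluster_names = assign["consensus"].map(
        lambda v: "AMBIGUOUS" if v == AMBIGUOUS else f"C{int(v)}"
    )
    assign["cluster"] = cluster_names
    write_table(assign, outdir / "clusters.tsv", phash, config.seed,
                index_label="sample_id")
    done("cluster", t0, k=clusterer.k_,
         agreement=round(clusterer.agreement_score_, 4),
         n_consensus=int((assign["consensus"] != AMBIGUOUS).sum()))

    # ---- fingerprint + scores ---------------------------------------
    t0 = time.time()
    if candidate_genes is None:
        candidate_genes = list(norm.gene_ids)
    consensus_named = cluster_names[cluster_names != "AMBIGUOUS"]
    # stability selection needs a handful of samples per class
    counts_by_cluster = consensus_named.value_counts()
    big = counts_by_cluster.index[counts_by_cluster >= 5]
    consensus_named = consensus_named[consensus_named.isin(big)]
    panel, freqs = fingerprint.stability_select(
        norm, consensus_named, candidate_genes, B=config.B,
        threshold=config.frequency_threshold,
        seed=stage_seed(config.seed, "fingerprint"),
    )
    if len(panel.gene_ids) == 0:
        raise RuntimeError(
            "stability selection returned an empty panel; consider a lower "
            "frequency_threshold or more bootstrap replicates"
        )
    ref = config.ref_cluster or _auto_ref_cluster(
        norm, consensus_named, panel.gene_ids, hv_ids
    )
    labels_with_hv = pd.concat(
        [consensus_named, pd.Series("HV", index=hv_ids)]
    )
    panel = fingerprint.split_directions(norm, labels_with_hv, panel,
                                         ref_cluster=ref)
    write_table(panel.table, outdir / "panel.tsv", phash, config.seed)
    scores = fingerprint.compute_scores(norm, hv_ids, panel)
    scores["cluster"] = labels_with_hv.reindex(scores.index)
    write_table(scores, outdir / "scores.tsv", phash, config.seed,
                index_label="sample_id")
    done("fingerprint", t0, panel_size=len(panel.gene_ids),
         G_up=panel.G_up, G_down=panel.G_down, ref_cluster=ref)

    # ---- differential expression ------------------------------------
    t0 = time.time()
    group = labels_with_hv.reindex(norm.sample_ids).dropna()
    de_sets = {}
    for c in sorted(consensus_named.unique()):
        de = diffex.de_analysis(norm, group, ("HV", c),
                                fc_min=config.fc_min, fdr_max=config.fdr_max)
        write_table(de, outdir / f"de_{c}_vs_HV.tsv", phash, config.seed)
        de_sets[c] = set(de.index[de["call"] != "NS"])
    partition = diffex.overlap_sets(de_sets) if len(de_sets) >= 2 else {}
    overlap = pd.DataFrame(
        [{"groups": "+".join(sorted(k)), "n_genes": len(v)}
         for k, v in sorted(partition.items(), key=lambda kv: sorted(kv[0]))]
    )
    write_table(overlap, outdir / "de_overlap.tsv", phash, config.seed,
                index=False)
    done("diffex", t0, **{f"n_de_{c}": len(s) for c, s in de_sets.items()})

    # ---- associations ------------------------------------------------
    t0 = time.time()
    feats = []
    score_cols = scores[["z_up", "z_down"]]
    ameta = meta.copy()
    ameta["cluster"] = labels_with_hv.reindex(meta.index).fillna("AMBIGUOUS")
    feats.append("cluster")
    if {"neutrophils", "b_cells", "t_cells"}.issubset(meta.columns):
        ameta["nlr"] = assoc.nlr(meta["neutrophils"], meta["b_cells"],
                                 meta["t_cells"])
        feats += ["neutrophils", "b_cells", "t_cells", "nlr"]
    atab = assoc.association_table(score_cols, ameta, feats)
    write_table(atab, outdir / "associations.tsv", phash, config.seed,
                index=False)
    done("assoc", t0, n_tests=len(atab))

    # ---- PLS-DA ------------------------------------------------------
    t0 = time.time()
    lab = consensus_named
    model = plsda.fit_plsda(norm.data[lab.index].T, lab.to_numpy())
    pls_scores = pd.DataFrame(model.x_scores_, index=lab.index,
                              columns=["comp1", "comp2"])
    pls_scores["label"] = lab
    write_table(pls_scores, outdir / "plsda_scores.tsv", phash, config.seed,
                index_label="sample_id")
    done("plsda", t0, n_samples=len(lab))

    # ---- preclinical reversal (optional) ----------------------------
    if config.preclinical is not None or config.simulate:
        t0 = time.time()
        pc = synthgen.PreclinicalConfig(
            **{**(config.preclinical or {}),
               "seed": stage_seed(config.seed, "preclinical")}
        )
        pmat, pmeta, ptruth = synthgen.gen_preclinical(pc)
        synthgen.write_dataset(outdir / "inputs_preclinical", pmat, pmeta, ptruth)
        pnorm, _ = exprprep.normalize(pmat)
        pnorm, _ = exprprep.filter_genes(pnorm)
        rep = diffex.reversal_analysis(
            pnorm, pmeta["arm"], control=pc.control_arm, disease=pc.disease_arm,
            fc_min=config.fc_min, fdr_max=config.fdr_max,
        )
        (outdir / "reversal.json").write_text(json.dumps({
            "n_pathology_up": len(rep.pathology_up),
            "n_pathology_down": len(rep.pathology_down),
            "reversal_fraction": rep.reversal_fraction,
            "reversed_by_arm": rep.reversed_by_arm,
        }, indent=2, sort_keys=True))
        done("reversal", t0, n_pathology=len(rep.pathology_genes),
             **{f"frac_{a}": round(f, 4)
                for a, f in rep.reversal_fraction.items()})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
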