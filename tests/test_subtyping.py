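"""Consensus clustering: recovery on separated blobs, label alignment
against brute force, consensus rules and classifier extension."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import lfp
from lfp.subtyping import (
    align_labels,
    cluster_three_ways,
    consensus,
    extend_to_test,
    select_k,
)


def make_blobs(rng, n_per=20, sep=10.0, d=30):
    # centers are distinct random profiles so both Euclidean and
    # sample-correlation distances separate the groups
    centers = rng.normal(scale=sep / np.sqrt(d), size=(3, d)) * np.sqrt(2)
    X = np.vstack([c + rng.normal(size=(n_per, d)) for c in centers])
    y = np.repeat([1, 2, 3], n_per)
    return X, y


class TestClusterThreeWays:
    def test_separated_blobs_recovered_by_each_method(self, rng):
        X, y = make_blobs(rng)
        labs = cluster_three_ways(X, 3, seed=0)
        for m in labs.columns:
            assert adjusted_rand_score(y, labs[m]) == 1.0

    def test_deterministic_repeat(self, rng):
        X, _ = make_blobs(rng)
        l1 = cluster_three_ways(X, 3, seed=4)
        l2 = cluster_three_ways(X, 3, seed=4)
        assert l1.equals(l2)

    def test_duplicated_sample_co_clustered_by_hclust(self, rng):
        X, _ = make_blobs(rng, n_per=8)
        X = np.vstack([X, X[0]])  # duplicate first sample
        labs = cluster_three_ways(X, 3, seed=1)
        assert labs["hclust"].iloc[0] == labs["hclust"].iloc[-1]

    def test_k_out_of_range_rejected(self, rng):
        X, _ = make_blobs(rng, n_per=2)
        with pytest.raises(ValueError):
            cluster_three_ways(X, 7, seed=0)


class TestAlignLabels:
    def test_permuted_labels_map_back_exactly(self):
        ref = np.array([1, 1, 2, 2, 3, 3])
        lab = np.array([3, 3, 1, 1, 2, 2])
        assert (align_labels(ref, lab) == ref).all()

    def test_matches_exhaustive_bijection_search(self, rng):
        """Agreement after alignment equals the best over all k!
        bijections; checked on the 9-sample one-discordant case and on
        random label vectors with k <= 4."""
        ref = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        lab = np.array([2, 2, 2, 3, 3, 1, 1, 1, 1])  # one discordant sample
        aligned = align_labels(ref, lab)
        agree = (aligned == ref).mean()
        best = max(
            (np.array([dict(zip([1, 2, 3], p))[v] for v in lab]) == ref).mean()
            for p in itertools.permutations([1, 2, 3])
        )
        assert agree == best == pytest.approx(8 / 9)
        for _ in range(20):
            k = int(rng.integers(2, 5))
            ref_r = rng.integers(1, k + 1, size=12)
            lab_r = rng.integers(1, k + 1, size=12)
            agree = (align_labels(ref_r, lab_r) == ref_r).mean()
            brute = max(
                (np.array([dict(zip(range(1, k + 1), p))[v] for v in lab_r])
                 == ref_r).mean()
                for p in itertools.permutations(range(1, k + 1))
            )
            assert agree == pytest.approx(brute)

    def test_padding_handles_unequal_label_counts(self):
        ref = np.array([1, 1, 2, 2])
        lab = np.array([1, 2, 3, 3])
        out = align_labels(ref, lab)
        assert len(np.unique(out)) == 3  # no labels collapsed


class TestConsensus:
    def test_unanimous_and_single_disagreement(self):
        a = np.array([1, 2, 3, 1])
        assert (consensus(a, a, a) == a).all()
        b = a.copy()
        b[2] = 1
        out = consensus(a, b, a)
        assert out[2] == lfp.AMBIGUOUS
        assert (out != lfp.AMBIGUOUS).sum() == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus([1, 2], [1, 2, 3], [1, 2, 3])


class TestSelectK:
    def test_three_blobs_select_three(self, rng):
        X, _ = make_blobs(rng, n_per=15)
        k, per_k, low = select_k(X, range(2, 6), seed=0)
        assert k == 3
        assert not low

    def test_single_blob_flags_low_agreement(self, rng):
        X = rng.normal(size=(40, 6))
        with pytest.warns(UserWarning, match="low clustering agreement"):
            _, per_k, low = select_k(X, range(2, 6), seed=0)
        assert low
        assert max(per_k.values()) < 0.5

    def test_singleton_range_trivial(self, rng):
        X, _ = make_blobs(rng, n_per=10)
        k, per_k, _ = select_k(X, [3], seed=0)
        assert k == 3 and set(per_k) == {3}

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(size=(10, 3)), [], seed=0)


class TestExtension:
    def test_training_duplicate_gets_its_label_confidently(self, rng):
        X, y = make_blobs(rng)
        res = extend_to_test(X, y, X[[0, 25, 45]], tau=0.6, seed=0)
        assert res.table["label"].tolist() == [y[0], y[25], y[45]]
        assert (res.table["confidence"] > 0.9).all()
        assert res.table["retained"].all()

    def test_tau_zero_retains_all(self, rng):
        X, y = make_blobs(rng, n_per=10)
        res = extend_to_test(X, y, rng.normal(size=(5, X.shape[1])), tau=0.0, seed=0)
        assert res.table["retained"].all()

    def test_tau_above_one_rejected(self, rng):
        X, y = make_blobs(rng, n_per=10)
        with pytest.raises(ValueError):
            extend_to_test(X, y, X[:2], tau=1.0 + 1e-9, seed=0)

    def test_missing_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.full(10, lfp.AMBIGUOUS)
        y[:5] = 1
        with pytest.raises(ValueError):
            extend_to_test(X, y, X[:2], seed=0)


class TestConsensusClusterer:
    def test_partition_invariant_to_sample_permutation(self, rng):
        X, y = make_blobs(rng)
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))])
        c1 = lfp.ConsensusClusterer(n_clusters=3, random_state=0).fit(df)
        perm = rng.permutation(len(df))
        c2 = lfp.ConsensusClusterer(n_clusters=3, random_state=0).fit(df.iloc[perm])
        lab1 = pd.Series(c1.labels_, index=df.index)
        lab2 = pd.Series(c2.labels_, index=df.index[perm]).reindex(df.index)
        assert adjusted_rand_score(lab1, lab2) == 1.0

    def test_recovery_monotone_in_effect_size(self):
        """Median consensus-vs-truth ARI never decreases along the
        planted effect grid 0, 0.5, 1.0, 2.0."""
        medians = []
        for eff in [0.0, 0.5, 1.0, 2.0]:
            aris = []
            for seed in range(4):
                cfg = lfp.CohortConfig(
                    n_hv=10, n_per_cluster={"C1": 18, "C2": 24, "C3": 12},
                    n_genes=800, n_candidates=60, n_fingerprint_up=20,
                    n_fingerprint_down=10,
                    effect_sizes={"C1": eff / 2, "C2": 0.0, "C3": eff},
                    seed=seed,
                )
                matrix, meta, _ = lfp.gen_cohort(cfg)
                norm, _ = lfp.normalize(matrix)
                pats = meta.index[meta["role"] == "patient"]
                clus = lfp.ConsensusClusterer(n_clusters=3, random_state=seed)
                labels = clus.fit_predict(norm.data[list(pats)].T)
                mask = labels != lfp.AMBIGUOUS
                if mask.sum() > 10:
                    aris.append(adjusted_rand_score(
                        meta.loc[pats, "cluster"][mask], labels[mask]))
                else:
                    aris.append(0.0)
            medians.append(float(np.median(aris)))
        assert all(b >= a - 0.05 for a, b in zip(medians, medians[1:]))
        assert medians[-1] > 0.9
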