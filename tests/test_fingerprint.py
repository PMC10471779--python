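"""Panel assembly, stability selection behavior, directions and the
median-deviation scores."""

import numpy as np
import pandas as pd
import pytest

import lfp
from lfp.fingerprint import StabilitySelector, score, score_samples


def _norm_matrix(rng, n_genes, n_samples, prefix="g"):
    vals = rng.normal(5, 1, size=(n_genes, n_samples))
    return lfp.ExpressionMatrix(
        pd.DataFrame(vals, index=[f"{prefix}{i}" for i in range(n_genes)],
                     columns=[f"s{i}" for i in range(n_samples)]),
        layer="normalized",
    )


class TestAssembleInteractants:
    def test_union_and_absent_counts(self):
        merged, absent = lfp.assemble_interactants(
            ["A", "B"], ["B", "C", "D"], dataset_genes=["A", "C", "X"]
        )
        assert merged == ["A", "B", "C", "D"]
        assert absent == ["B", "D"]

    def test_case_insensitive_dedup(self):
        merged, _ = lfp.assemble_interactants(["Lgals3", "CD98"],
                                              ["LGALS3", "itgb1"], ["LGALS3"])
        assert merged == ["LGALS3", "CD98", "ITGB1"]

    def test_database_merge_arithmetic(self, rng):
        """Two lists of 210 and 276 symbols overlapping in 179 merge to
        307; removing 59 absent symbols leaves 248 candidates."""
        symbols = [f"SYM{i:04d}" for i in range(400)]
        shared = symbols[:179]
        list_a = shared + symbols[179 : 179 + 31]          # 210
        list_b = shared + symbols[210 : 210 + 97]          # 276
        merged, _ = lfp.assemble_interactants(list_a, list_b, symbols)
        assert len(merged) == 210 + 276 - 179 == 307
        dataset = merged[59:]
        merged2, absent = lfp.assemble_interactants(list_a, list_b, dataset)
        assert len(absent) == 59
        assert len(merged2) - len(absent) == 248

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            lfp.assemble_interactants([], ["A"], ["A"])


class TestStabilitySelector:
    def test_single_strong_gene_always_chosen(self, rng):
        """A gene with 3-log2 cluster separation among 200 noise genes
        reaches selection frequency 1.0 at B=25."""
        n_per = 20
        y = np.repeat(["a", "b"], n_per)
        X = rng.normal(5, 0.5, size=(2 * n_per, 201))
        X[n_per:, 0] += 3.0
        cols = ["signal"] + [f"noise{i}" for i in range(200)]
        sel = StabilitySelector(B=25, threshold=1.0, random_state=0).fit(
            pd.DataFrame(X, columns=cols), y
        )
        assert sel.frequencies_["signal"] == 1.0
        assert "signal" in sel.selected_genes_

    def test_pure_noise_rarely_selected(self, rng):
        y = np.repeat(["a", "b"], 15)
        X = rng.normal(size=(30, 120))
        sel = StabilitySelector(B=25, threshold=1.0, random_state=1).fit(
            pd.DataFrame(X, columns=[f"n{i}" for i in range(120)]), y
        )
        assert len(sel.selected_genes_) <= 1

    def test_frequency_invariant_to_candidate_order(self, rng):
        y = np.repeat(["a", "b"], 12)
        X = rng.normal(size=(24, 30))
        X[12:, 3] += 2.5
        df = pd.DataFrame(X, columns=[f"g{i:02d}" for i in range(30)])
        s1 = StabilitySelector(B=8, random_state=3).fit(df, y)
        perm = rng.permutation(30)
        s2 = StabilitySelector(B=8, random_state=3).fit(df.iloc[:, perm], y)
        pd.testing.assert_series_equal(
            s1.frequencies_.sort_index(), s2.frequencies_.sort_index()
        )

    def test_invalid_inputs_rejected(self, rng):
        y = np.repeat(["a", "b"], 10)
        df = pd.DataFrame(rng.normal(size=(20, 5)))
        with pytest.raises(ValueError):
            StabilitySelector(B=0).fit(df, y)
        with pytest.raises(ValueError):
            StabilitySelector(B=5).fit(df, np.repeat(["a", "b"], [18, 2]))


class TestSplitDirections:
    def test_signs_follow_reference_contrast(self, rng):
        em = _norm_matrix(rng, 4, 30)
        labels = pd.Series(
            ["C3"] * 10 + ["C1"] * 10 + ["HV"] * 10, index=em.sample_ids
        )
        em.data.loc["g0", labels == "C3"] += 2.0   # up in ref
        em.data.loc["g1", labels == "C3"] -= 2.0   # down in ref
        table = pd.DataFrame({"frequency": 1.0}, index=pd.Index(["g0", "g1"]))
        panel = lfp.FingerprintPanel(table, B=5, frequency_threshold=1.0)
        panel = lfp.split_directions(em, labels, panel, ref_cluster="C3")
        assert panel.table.loc["g0", "direction"] == 1
        assert panel.table.loc["g1", "direction"] == -1

    def test_empty_reference_rejected(self, rng):
        em = _norm_matrix(rng, 2, 6)
        labels = pd.Series(["C1"] * 6, index=em.sample_ids)
        table = pd.DataFrame({"frequency": 1.0}, index=pd.Index(["g0"]))
        panel = lfp.FingerprintPanel(table, B=5, frequency_threshold=1.0)
        with pytest.raises(ValueError, match="C3"):
            lfp.split_directions(em, labels, panel, ref_cluster="C3")

    def test_recovers_planted_directions(self, small_cohort_norm):
        norm, meta, truth = small_cohort_norm
        genes = truth.fingerprint_up + truth.fingerprint_down
        table = pd.DataFrame({"frequency": 1.0}, index=pd.Index(genes))
        panel = lfp.FingerprintPanel(table, B=5, frequency_threshold=1.0)
        panel = lfp.split_directions(norm, meta["cluster"], panel,
                                     ref_cluster="C3")
        hits = sum(
            panel.table.loc[g, "direction"] == 1 for g in truth.fingerprint_up
        ) + sum(
            panel.table.loc[g, "direction"] == -1 for g in truth.fingerprint_down
        )
        assert hits / len(genes) >= 0.95


class TestScore:
    def test_hand_computed_example(self):
        hv = pd.DataFrame(
            {"h1": [1, 2, 3, 4, 5], "h2": [1, 2, 3, 4, 5]},
            index=[f"g{i}" for i in range(5)],
        )
        sample = pd.Series([2, 4, 6, 8, 10], index=hv.index)
        # deviations (1, 2, 3, 4, 5) -> median 3
        assert score(sample, hv, list(hv.index)) == 3.0

    def test_identity_and_shift_equivariance(self, rng):
        hv = pd.DataFrame(rng.normal(size=(10, 7)),
                          index=[f"g{i}" for i in range(10)],
                          columns=[f"h{i}" for i in range(7)])
        med = hv.median(axis=1)
        assert score(med, hv, list(hv.index)) == 0.0
        assert score(med + 1.7, hv, list(hv.index)) == pytest.approx(1.7)

    def test_ignores_genes_outside_set_and_order(self, rng):
        hv = pd.DataFrame(rng.normal(size=(6, 5)),
                          index=[f"g{i}" for i in range(6)],
                          columns=[f"h{i}" for i in range(5)])
        sample = pd.Series(rng.normal(size=6), index=hv.index)
        subset = ["g1", "g3", "g4"]
        s1 = score(sample, hv, subset)
        s2 = score(sample, hv, subset[::-1])
        sample2 = sample.copy()
        sample2["g0"] = 99.0
        s3 = score(sample2, hv, subset)
        assert s1 == s2 == s3

    def test_missing_gene_named(self, rng):
        hv = pd.DataFrame(rng.normal(size=(2, 3)), index=["g0", "g1"],
                          columns=["h0", "h1", "h2"])
        with pytest.raises(KeyError, match="gX"):
            score(pd.Series({"g0": 1.0, "g1": 2.0}), hv, ["g0", "gX"])
        with pytest.raises(ValueError):
            score(pd.Series({"g0": 1.0}), hv, [])

    def test_vectorized_matches_scalar(self, rng):
        em = _norm_matrix(rng, 8, 12)
        hv_ids = list(em.sample_ids[:5])
        genes = list(em.gene_ids[:4])
        vec = score_samples(em, hv_ids, genes)
        for s in em.sample_ids[5:8]:
            assert vec[s] == pytest.approx(
                score(em.data[s], em.data[hv_ids], genes)
            )


class TestZNormalization:
    def test_hand_example(self):
        z = lfp.z_normalize_scores([3.0], [0.0, 2.0])
        assert z[0] == pytest.approx((3 - 1) / np.sqrt(2.0))

    def test_self_standardization(self, rng):
        hv = rng.normal(size=40)
        z = lfp.z_normalize_scores(hv, hv)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert lfp.z_normalize_scores([hv.mean()], hv)[0] == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            lfp.z_normalize_scores([1.0], [2.0, 2.0])
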