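"""Stage similarity matrices, hierarchical ordering, hourglass extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirglass.annotation_io import ExpressionMatrix
from mirglass import stagecompare as sc


def _rpm(data: dict, index=None, species="spcA") -> ExpressionMatrix:
    df = pd.DataFrame(data)
    if index is not None:
        df.index = index
    df = df * (1e6 / df.sum(axis=0))
    return ExpressionMatrix(data=df, unit="rpm", species=species)


class TestSpearmanRho:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ])
    def test_frozen_examples(self, x, y, expected):
        assert sc.spearman_rho(x, y) == pytest.approx(expected)

    def test_agrees_with_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.random(15)
            y = np.round(rng.random(15), 1)  # ties
            assert sc.spearman_rho(x, y) == pytest.approx(
                sc.pearson_of_ranks(x, y), abs=1e-12)

    def test_constant_or_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sc.spearman_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="3 obs"):
            sc.spearman_rho([1, 2], [1, 2])

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho = sc.spearman_rho(x, y)
        assert sc.spearman_rho(np.exp(x), y) == pytest.approx(rho, abs=1e-12)
        assert sc.spearman_rho(x, 3 * y + 7) == pytest.approx(rho, abs=1e-12)
        assert sc.spearman_rho(x, y ** 3) == pytest.approx(rho, abs=1e-12)


class TestCorrelationMatrix:
    def test_within_species_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        m = _rpm({f"s{i}": rng.random(8) + 0.1 for i in range(4)},
                 index=[f"g{i}-5p" for i in range(8)])
        res = sc.correlation_matrix(m, m)
        v = res.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert (np.abs(v) <= 1 + 1e-12).all()

    def test_euclidean_z_zero_diagonal(self):
        rng = np.random.default_rng(1)
        m = _rpm({f"s{i}": rng.random(8) + 0.1 for i in range(4)},
                 index=[f"g{i}-5p" for i in range(8)])
        res = sc.correlation_matrix(m, m, metric="euclidean_z")
        assert np.allclose(np.diag(res.values.to_numpy()), 0.0, atol=1e-9)

    def test_rank_identical_stages_correlate_perfectly(self):
        m_a = _rpm({"s1": [1.0, 2.0, 4.0], "s2": [10.0, 20.0, 40.0]},
                   index=["g1-5p", "g2-5p", "g3-5p"])
        m_b = _rpm({"t1": [5.0, 6.0, 9.0]}, index=["h1-5p", "h2-5p", "h3-5p"],
                   species="spcB")
        mapping = {"g1-5p": "h1-5p", "g2-5p": "h2-5p", "g3-5p": "h3-5p"}
        res = sc.correlation_matrix(m_a, m_b, mapping)
        assert np.allclose(res.values.to_numpy(), 1.0)

    def test_swapping_arguments_transposes(self):
        rng = np.random.default_rng(3)
        m_a = _rpm({f"s{i}": rng.random(6) + 0.1 for i in range(3)},
                   index=[f"g{i}-5p" for i in range(6)])
        m_b = _rpm({f"t{i}": rng.random(6) + 0.1 for i in range(4)},
                   index=[f"h{i}-5p" for i in range(6)], species="spcB")
        fwd = {f"g{i}-5p": f"h{i}-5p" for i in range(6)}
        rev = {v: k for k, v in fwd.items()}
        ab = sc.correlation_matrix(m_a, m_b, fwd).values.to_numpy()
        ba = sc.correlation_matrix(m_b, m_a, rev).values.to_numpy()
        assert np.allclose(ab, ba.T)

    def test_too_few_shared_rows_rejected(self):
        m = _rpm({"s1": [1.0, 2.0]}, index=["g1-5p", "g2-5p"])
        with pytest.raises(ValueError, match=">= 3"):
            sc.correlation_matrix(m, m)

    def test_requires_rpm(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=list("abc"))
        raw = ExpressionMatrix(data=df, unit="raw_fractional_count")
        with pytest.raises(ValueError, match="RPM"):
            sc.correlation_matrix(raw, raw)


class TestReplicateSpread:
    def test_mean_and_sd_of_per_replicate_coefficients(self):
        # replicate 1 vs B gives rho = 0.8, replicate 2 gives rho = 1.0
        b = _rpm({"t1": [1.0, 2.0, 3.0, 4.0]},
                 index=[f"h{i}-5p" for i in range(4)], species="spcB")
        rep1 = _rpm({"s1": [1.0, 3.0, 2.0, 4.0]},
                    index=[f"g{i}-5p" for i in range(4)])
        rep2 = _rpm({"s1": [1.0, 2.0, 3.0, 4.0]},
                    index=[f"g{i}-5p" for i in range(4)])
        mapping = {f"g{i}-5p": f"h{i}-5p" for i in range(4)}
        res = sc.replicate_spread([rep1, rep2], b, mapping)
        assert res.values.loc["s1", "t1"] == pytest.approx(0.9)
        assert res.replicate_sd.loc["s1", "t1"] == pytest.approx(
            np.std([0.8, 1.0], ddof=1))

    def test_identical_replicates_have_zero_sd(self):
        b = _rpm({"t1": [1.0, 2.0, 3.0]}, index=list("xyz"), species="spcB")
        rep = _rpm({"s1": [2.0, 4.0, 9.0]}, index=list("abc"))
        mapping = dict(zip("abc", "xyz"))
        res = sc.replicate_spread([rep, rep], b, mapping)
        assert res.replicate_sd.loc["s1", "t1"] == 0.0

    def test_single_replicate_leaves_sd_unset(self, caplog):
        import logging
        b = _rpm({"t1": [1.0, 2.0, 3.0]}, index=list("xyz"), species="spcB")
        rep = _rpm({"s1": [2.0, 4.0, 9.0]}, index=list("abc"))
        with caplog.at_level(logging.WARNING):
            res = sc.replicate_spread([rep], b, dict(zip("abc", "xyz")))
        assert res.replicate_sd is None


def brute_force_leaf_order(D: np.ndarray, labels: list[str]) -> list[str]:
    """Average-linkage oracle recomputing every cluster distance from scratch
    as the mean of all cross pairs in the ORIGINAL distance matrix."""
    clusters = [[i] for i in range(len(labels))]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return [labels[k] for k in clusters[0]]


class TestHcluster:
    def _result(self, values, labels):
        df = pd.DataFrame(values, index=labels, columns=labels)
        return sc.StageCorrelationResult(values=df, metric="spearman")

    def test_most_similar_pair_ends_up_adjacent(self):
        rho = np.array([[1.0, 0.99, 0.1],
                        [0.99, 1.0, 0.1],
                        [0.1, 0.1, 1.0]])
        res = sc.hcluster(self._result(rho, ["s1", "s2", "s3"]))
        i1, i2 = res.row_order.index("s1"), res.row_order.index("s2")
        assert abs(i1 - i2) == 1

    def test_single_stage_trivial_order(self):
        res = sc.hcluster(self._result([[1.0]], ["only"]))
        assert res.row_order == ["only"]

    def test_non_symmetric_input_rejected(self):
        df = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=["a", "b"],
                          columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            sc.hcluster(sc.StageCorrelationResult(values=df, metric="spearman"))

    def test_matches_from_scratch_average_linkage_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(15):
            n = int(rng.integers(2, 7))
            rho = rng.uniform(-0.5, 1.0, size=(n, n))
            rho = (rho + rho.T) / 2
            np.fill_diagonal(rho, 1.0)
            labels = [f"s{i}" for i in range(n)]
            res = sc.hcluster(self._result(rho, labels))
            D = 1.0 - rho
            np.fill_diagonal(D, 0.0)
            assert res.row_order == brute_force_leaf_order(D, labels)

    def test_merge_heights_agree_with_scipy(self):
        """Cross-check cluster merge structure against scipy's UPGMA on a
        tie-free matrix (cophenetic distances must coincide)."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(12)
        n = 6
        rho = rng.uniform(-0.5, 0.99, size=(n, n))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        D = 1.0 - rho
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        labels = [f"s{i}" for i in range(n)]
        # same pairwise cophenetic distances -> same dendrogram topology
        my_order = sc.hcluster(
            sc.StageCorrelationResult(
                values=pd.DataFrame(rho, index=labels, columns=labels),
                metric="spearman")).row_order
        assert set(my_order) == set(labels)
        coph = squareform(cophenet(Z))
        oracle_order = brute_force_leaf_order(D, labels)
        assert my_order == oracle_order
        # adjacent leaves in our order merge below the max cophenetic height
        idx = {lab: k for k, lab in enumerate(labels)}
        for a, b in zip(my_order[:-1], my_order[1:]):
            assert coph[idx[a], idx[b]] <= coph.max()


class TestHourglassProfile:
    def _cross(self, diagonal):
        n = len(diagonal)
        rows = [f"a{i}" for i in range(n)]
        cols = [f"b{i}" for i in range(n)]
        values = np.full((n, n), -1.0)
        np.fill_diagonal(values, diagonal)
        df = pd.DataFrame(values, index=rows, columns=cols)
        res = sc.StageCorrelationResult(values=df, metric="spearman")
        return res, [(f"a{i}", f"b{i}") for i in range(n)]

    def test_frozen_toy_diagonal(self):
        res, pairs = self._cross([0.7, 0.9, 0.95, 0.9, 0.6])
        hp = sc.hourglass_profile(res, pairs)
        assert hp.mid_indices == [1, 2, 3]
        assert hp.argmax_index == 2
        assert hp.score == pytest.approx(np.mean([0.9, 0.95, 0.9])
                                         - np.mean([0.7, 0.6]))

    def test_constant_diagonal_scores_zero_argmax_first(self):
        res, pairs = self._cross([0.5] * 5)
        hp = sc.hourglass_profile(res, pairs)
        assert hp.score == 0.0
        assert hp.argmax_index == 0

    def test_monotone_decreasing_diagonal(self):
        res, pairs = self._cross([0.9, 0.5, 0.45, 0.42, 0.4])
        hp = sc.hourglass_profile(res, pairs)
        assert hp.argmax_index == 0
        assert hp.score < 0

    def test_best_partner_tracks_maximum(self):
        res, pairs = self._cross([0.7, 0.9, 0.95])
        hp = sc.hourglass_profile(res, pairs)
        assert hp.best_partner_for_a["a1"] == "b1"
        assert hp.best_partner_for_b["b2"] == "a2"

    def test_fewer_than_three_pairs_rejected(self):
        res, pairs = self._cross([0.7, 0.9])
        with pytest.raises(ValueError, match=">= 3"):
            sc.hourglass_profile(res, pairs)
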