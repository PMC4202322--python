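"""Alignment, p-distance, divergence annotation, rate tertiles, clustering."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirglass import homology
from mirglass.annotation_io import OrthologPair
from mirglass.homology import (
    PairwiseAlignment,
    align_pair,
    annotate_divergence,
    classify_rates,
    find_clusters,
    substitutions_per_site,
)
from mirglass.synthetic_data import mutate_sequence

from conftest import make_locus


# --- independent oracles ----------------------------------------------------

def score_alignment(row_a: str, row_b: str, scoring=homology.DEFAULT_SCORING) -> float:
    """Score a given alignment directly: match/mismatch columns plus
    gap_open + len * gap_extend per gap run."""
    match, mismatch, go, ge = scoring
    score = 0.0
    for row in (row_a, row_b):
        in_gap = False
        for ch in row:
            if ch == "-":
                if not in_gap:
                    score += go
                score += ge
                in_gap = True
            else:
                in_gap = False
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            score += match if ca == cb else mismatch
    return score


def brute_force_best_score(a: str, b: str, scoring=homology.DEFAULT_SCORING) -> float:
    """Enumerate every global alignment (no double-gap columns) and return
    the best score.  Exponential; only for tiny sequences."""
    best = -np.inf

    def rec(i, j, ra, rb):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score_alignment(ra, rb, scoring))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ra + a[i], rb + b[j])
        if i < len(a):
            rec(i + 1, j, ra + a[i], rb + "-")
        if j < len(b):
            rec(i, j + 1, ra + "-", rb + b[j])

    rec(0, 0, "", "")
    return best


class TestAlignPair:
    def test_identical_sequences(self):
        aln = align_pair("ACGU", "ACGU")
        assert aln.score == 4.0
        assert aln.aligned_a == aln.aligned_b

    def test_single_mismatch_beats_gapping(self):
        aln = align_pair("ACGU", "ACGA")
        assert aln.score == 2.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_terminal_gap(self):
        aln = align_pair("ACGU", "ACG")
        assert aln.aligned_b.endswith("-") or aln.aligned_b.startswith("-")
        assert aln.score == brute_force_best_score("ACGT", "ACG")

    def test_rows_reproduce_inputs_and_score_is_self_consistent(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            aln = align_pair(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b
            assert score_alignment(aln.aligned_a, aln.aligned_b) == pytest.approx(
                aln.score)

    def test_matches_exhaustive_enumeration_on_short_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            assert align_pair(a, b).score == pytest.approx(
                brute_force_best_score(a, b)), (a, b)

    def test_matches_biopython_global_scores(self):
        """Independent cross-check against Bio.Align.PairwiseAligner with the
        equivalent affine parameterisation."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        # our convention charges open + extend on the first gap residue
        aligner.open_gap_score = -7
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 60)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 60)))
            assert align_pair(a, b).score == pytest.approx(aligner.score(a, b))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            align_pair("", "ACGU")
        with pytest.raises(ValueError, match="non-nucleotide"):
            align_pair("ACGX", "ACGU")


class TestSubstitutionsPerSite:
    def test_examples(self):
        assert substitutions_per_site(PairwiseAlignment("A" * 22, "A" * 22, 0)) == 0.0
        assert substitutions_per_site(PairwiseAlignment("ACGT", "ACGA", 0)) == 0.25
        assert substitutions_per_site(PairwiseAlignment("ACG-T", "ACGAT", 0)) == 0.0

    def test_u_and_t_are_identical(self):
        assert substitutions_per_site(PairwiseAlignment("ACGU", "ACGT", 0)) == 0.0

    def test_all_gap_columns_undefined(self):
        with pytest.raises(ValueError, match="gap-free"):
            substitutions_per_site(PairwiseAlignment("A--", "-CC", 0))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_in_rows(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = mutate_sequence(a, 0.2, rng)
        aln = align_pair(a, b)
        assert substitutions_per_site(aln) == substitutions_per_site(
            PairwiseAlignment(aln.aligned_b, aln.aligned_a, aln.score))

    def test_estimator_recovers_simulated_rate(self):
        """p-distance on no-indel simulated pairs stays within 3 binomial SD
        of the true per-site substitution probability."""
        rng = np.random.default_rng(11)
        p, L = 0.1, 600
        hits = 0
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=L))
            b = mutate_sequence(a, p, rng)
            est = substitutions_per_site(align_pair(a, b))
            hits += abs(est - p) <= 3 * np.sqrt(p * (1 - p) / L)
        assert hits >= 29


class TestAnnotateDivergence:
    def _pair_with_arm_subs(self, subs_5p=1, subs_3p=0):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGU"), size=90))
        la = make_locus("a1", hairpin_seq=seq)
        seq_b = list(seq)
        # put substitutions inside the arms (A<->C keeps symbols valid)
        for k in range(subs_5p):
            i = 6 + k
            seq_b[i] = "C" if seq_b[i] != "C" else "G"
        for k in range(subs_3p):
            i = 64 + k
            seq_b[i] = "C" if seq_b[i] != "C" else "G"
        lb = make_locus("b1", species="spcB", hairpin_seq="".join(seq_b))
        return la, lb, OrthologPair(id_a="a1", id_b="b1")

    def test_identical_pair_is_zero_zero(self):
        la, lb, pair = self._pair_with_arm_subs(0, 0)
        lb = make_locus("b1", species="spcB", hairpin_seq=la.hairpin_seq)
        annotate_divergence([pair], [la], [lb])
        assert pair.hairpin_div == 0.0
        assert pair.mature_div == 0.0

    def test_mature_divergence_pools_sites_over_both_arms(self):
        la, lb, pair = self._pair_with_arm_subs(subs_5p=1, subs_3p=0)
        annotate_divergence([pair], [la], [lb])
        assert pair.mature_div == pytest.approx(1 / 44)

    def test_single_shared_arm_uses_that_arm_alone(self):
        la, lb, pair = self._pair_with_arm_subs(subs_5p=1, subs_3p=0)
        del lb.mature_intervals["3p"], lb.mature_seqs["3p"]
        annotate_divergence([pair], [la], [lb])
        assert pair.mature_div == pytest.approx(1 / 22)

    def test_missing_hairpin_sequence_is_an_error(self):
        la, lb, pair = self._pair_with_arm_subs()
        lb.hairpin_seq = ""
        lb.mature_seqs = {}
        with pytest.raises(ValueError, match="hairpin"):
            annotate_divergence([pair], [la], [lb])


class TestClassifyRates:
    def _pairs(self, values):
        return [OrthologPair(id_a=f"a{i}", id_b=f"b{i}", hairpin_div=v)
                for i, v in enumerate(values)]

    def test_three_distinct_values(self):
        pairs = classify_rates(self._pairs([0.0, 0.1, 0.2]), "hairpin_div")
        assert [p.rate_class for p in pairs] == ["low", "medium", "high"]

    def test_nine_values_split_three_ways(self):
        pairs = classify_rates(self._pairs([i / 10 for i in range(9)]), "hairpin_div")
        from collections import Counter
        assert Counter(p.rate_class for p in pairs) == \
            {"low": 3, "medium": 3, "high": 3}

    def test_all_ties_split_deterministically(self):
        pairs = classify_rates(self._pairs([0.1] * 6), "hairpin_div")
        # stable sort on (value, id_a): a0,a1 low / a2,a3 medium / a4,a5 high
        assert [p.rate_class for p in pairs] == \
            ["low", "low", "medium", "medium", "high", "high"]

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            classify_rates(self._pairs([0.0, 0.1]), "hairpin_div")


# --- clustering -------------------------------------------------------------

def brute_force_clusters(loci, max_gap=10000):
    """All-pairs single-linkage oracle: union-find over locus pairs whose
    same-chrom same-strand gap is <= max_gap."""
    parent = {l.locus_id: l.locus_id for l in loci}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for la, lb in itertools.combinations(loci, 2):
        if (la.chrom, la.strand) != (lb.chrom, lb.strand):
            continue
        first, second = sorted([la, lb], key=lambda l: l.hairpin_interval)
        gap = second.hairpin_interval[0] - first.hairpin_interval[1]
        if gap <= max_gap:
            parent[find(la.locus_id)] = find(lb.locus_id)
    groups = {}
    for l in loci:
        groups.setdefault(find(l.locus_id), []).append(l)
    return {
        frozenset(x.locus_id for x in members)
        for members in groups.values()
    }


class TestFindClusters:
    def _two(self, gap, strand_b="+"):
        return [
            make_locus("m1", start=1000, strand="+"),
            make_locus("m2", start=1000 + 90 + gap, strand=strand_b),
        ]

    @pytest.mark.parametrize("gap,together", [(9999, True), (10000, True),
                                              (10001, False)])
    def test_ten_kb_boundary(self, gap, together):
        clusters = find_clusters(self._two(gap))
        n_multi = len(clusters.multi_member_clusters())
        assert (n_multi == 1) is together

    def test_opposite_strands_never_cluster(self):
        clusters = find_clusters(self._two(100, strand_b="-"))
        assert not clusters.multi_member_clusters()

    def test_matches_all_pairs_single_linkage_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(2, 20))
            loci = [
                make_locus(f"m{i}",
                           start=int(rng.integers(0, 200_000)),
                           strand="+" if rng.random() < 0.7 else "-",
                           chrom=f"chr{rng.integers(1, 3)}")
                for i in range(n)
            ]
            got = {frozenset(m) for m in find_clusters(loci).clusters.values()}
            assert got == brute_force_clusters(loci)

    def test_empty_input(self):
        assert find_clusters([]).clusters == {}
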