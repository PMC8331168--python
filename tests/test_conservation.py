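"""Distances, UPGMA, bootstrap, site mapping, window similarity, motif scan."""

import itertools
import math

import numpy as np
import pytest

from prmkit.conservation import (
    DistanceMatrix, MultipleAlignment, bootstrap_support, blosum62,
    distance_matrix, jc_distance, map_reference_position, motif_scan,
    p_distance, upgma, window_similarity,
)
from prmkit.errors import MotifError, SaturationError


class TestPDistance:
    def test_identical_rows(self, small_msa):
        msa = MultipleAlignment.from_pairs([("a", "MKRS"), ("b", "MKRS")])
        assert p_distance(msa, 0, 1) == 0.0

    def test_half_differing(self):
        msa = MultipleAlignment.from_pairs([("a", "MKRS"), ("b", "MKAG")])
        assert p_distance(msa, 0, 1) == 0.5

    def test_gap_column_excluded(self):
        msa = MultipleAlignment.from_pairs([("a", "AC-G"), ("b", "AT-G")])
        assert p_distance(msa, 0, 1) == pytest.approx(1 / 3)

    def test_no_comparable_sites_error(self):
        msa = MultipleAlignment.from_pairs([("a", "A--"), ("b", "-AA")])
        with pytest.raises(ValueError):
            p_distance(msa, 0, 1)


class TestJcDistance:
    def test_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_at_p01(self):
        assert jc_distance(0.1, k=20) == pytest.approx(0.10566, abs=1e-5)

    def test_equals_closed_form_everywhere(self):
        for p in np.linspace(0.0, 0.94, 50):
            expected = -(19 / 20) * math.log(1 - (20 / 19) * p)
            assert jc_distance(p) == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_small_p_limit(self):
        for p in (1e-6, 1e-4, 1e-3):
            assert jc_distance(p) - p == pytest.approx(0.0, abs=1e-5)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jc_distance(0.95)


def naive_upgma(labels, d):
    """Independent O(n^3) UPGMA for cross-checking: returns cophenetic distances."""
    clusters = {i: frozenset([lab]) for i, lab in enumerate(labels)}
    dist = {
        frozenset((i, j)): d[i][j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    sizes = {i: 1 for i in clusters}
    heights = {}
    nxt = len(labels)
    coph = {}
    while len(clusters) > 1:
        def key(pair):
            i, j = tuple(pair)
            reps = sorted([min(clusters[i]), min(clusters[j])])
            return (dist[pair], tuple(reps))

        best = min(dist, key=key)
        i, j = tuple(best)
        h = dist[best] / 2
        for a in clusters[i]:
            for b in clusters[j]:
                coph[tuple(sorted((a, b)))] = 2 * h
        m = nxt
        nxt += 1
        clusters[m] = clusters[i] | clusters[j]
        sizes[m] = sizes[i] + sizes[j]
        for k in list(clusters):
            if k in (i, j, m):
                continue
            dist[frozenset((k, m))] = (
                sizes[i] * dist[frozenset((i, k))] + sizes[j] * dist[frozenset((j, k))]
            ) / (sizes[i] + sizes[j])
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        del clusters[i], clusters[j], sizes[i], sizes[j]
    return coph


class TestUpgma:
    def test_two_taxa(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.2], [0.2, 0]]))
        tree = upgma(dm)
        assert tree.height == pytest.approx(0.1)
        assert tree.leaf_labels() == frozenset({"A", "B"})

    def test_three_taxa_hand_execution(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]),
        )
        tree = upgma(dm)
        assert tree.height == pytest.approx(0.3)
        (inner,) = [c for c in tree.children if not c.is_leaf]
        assert inner.height == pytest.approx(0.1)
        assert inner.leaf_labels() == frozenset({"A", "B"})

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A", "B"], np.array([[0, 0.2], [0.3, 0]])))

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        labels = list("ABCDEF")
        for _ in range(200):
            d = rng.uniform(0.05, 1.0, size=(6, 6))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = upgma(DistanceMatrix(labels, d))
            expected = naive_upgma(labels, d.tolist())
            got = tree.cophenetic()
            assert got.keys() == expected.keys()
            for pair in expected:
                assert got[pair] == pytest.approx(expected[pair], rel=1e-12)

    def test_ultrametric_input_recovered_exactly(self):
        rng = np.random.default_rng(12)
        labels = list("ABCDEF")
        for _ in range(50):
            # random ultrametric matrix from a random tree built by random merges
            heights = np.sort(rng.uniform(0.1, 1.0, size=5))
            clusters = [{lab} for lab in labels]
            d = {}
            for h in heights:
                i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
                for a in clusters[i]:
                    for b in clusters[j]:
                        d[tuple(sorted((a, b)))] = 2 * h
                clusters[i] = clusters[i] | clusters[j]
                del clusters[j]
            mat = np.zeros((6, 6))
            for (a, b), v in d.items():
                ia, ib = labels.index(a), labels.index(b)
                mat[ia, ib] = mat[ib, ia] = v
            tree = upgma(DistanceMatrix(labels, mat))
            coph = tree.cophenetic()
            for (a, b), v in d.items():
                assert coph[(a, b)] == pytest.approx(v, rel=1e-12)


class TestBootstrap:
    def test_covarying_blocks_get_full_support(self, covarying_msa):
        tree = bootstrap_support(covarying_msa, n_reps=200, seed=4)
        clades = {frozenset(k): node.support for k, node in tree.clades().items()}
        assert clades[frozenset({"T0", "T1", "T2"})] == 100.0
        assert clades[frozenset({"T3", "T4", "T5"})] == 100.0

    def test_single_replicate_supports_are_binary(self, small_msa):
        tree = bootstrap_support(small_msa, n_reps=1, seed=9)
        sups = {n.support for n in tree.clades().values() if n.support is not None}
        assert sups <= {0.0, 100.0}

    def test_same_seed_reproducible(self, small_msa):
        t1 = bootstrap_support(small_msa, n_reps=50, seed=21)
        t2 = bootstrap_support(small_msa, n_reps=50, seed=21)
        s1 = {k: n.support for k, n in t1.clades().items()}
        s2 = {k: n.support for k, n in t2.clades().items()}
        assert s1 == s2

    def test_taxon_order_invariance(self, covarying_msa):
        reordered = MultipleAlignment.from_pairs(
            [
                (i, "".join(r))
                for i, r in sorted(
                    zip(covarying_msa.ids, covarying_msa.rows), reverse=True
                )
            ]
        )
        t1 = bootstrap_support(covarying_msa, n_reps=100, seed=5)
        t2 = bootstrap_support(reordered, n_reps=100, seed=5)
        s1 = {k: n.support for k, n in t1.clades().items()}
        s2 = {k: n.support for k, n in t2.clades().items()}
        assert s1 == s2


class TestSiteMapping:
    def test_ungapped_reference_is_identity(self):
        msa = MultipleAlignment.from_pairs([("ref", "MKRS"), ("sp", "MKAS")])
        assert map_reference_position(msa, "ref", 4).column == 4

    def test_gapped_reference(self):
        msa = MultipleAlignment.from_pairs([("ref", "A-CS"), ("sp", "AGC-")])
        report = map_reference_position(msa, "ref", 3)
        assert report.column == 4
        assert report.residues["sp"] == "-"
        assert report.ser_present == {"ref": True, "sp": False}

    def test_position_beyond_reference_errors(self):
        msa = MultipleAlignment.from_pairs([("ref", "A-CS"), ("sp", "AGCT")])
        with pytest.raises(ValueError):
            map_reference_position(msa, "ref", 4)


class TestWindowSimilarity:
    def build(self, column):
        return MultipleAlignment.from_pairs(
            [(f"sp{i}", res) for i, res in enumerate(column)]
        )

    def test_identical_column_black(self):
        (col,) = window_similarity(self.build("SSSS"), [1])
        assert col.percent == 100.0 and col.category == "black"

    def test_conservative_substitution_counts_as_similar(self):
        assert blosum62("S", "T") == 1.0
        (col,) = window_similarity(self.build("SSST"), [1])
        assert col.percent == 100.0 and col.category == "black"

    def test_dissimilar_residue_drops_band(self):
        assert blosum62("S", "W") < 1.0
        (col,) = window_similarity(self.build("SSSW"), [1])
        assert col.percent == 75.0 and col.category == "light-grey"

    def test_band_edges_are_half_open(self):
        (c80,) = window_similarity(self.build("SSSSW"), [1])
        assert c80.percent == 80.0 and c80.category == "dark-grey"
        # consensus W (modal): 3/5 similar = exactly 60% -> light-grey (inclusive edge)
        (c60,) = window_similarity(self.build("SSWWW"), [1])
        assert c60.percent == 60.0 and c60.category == "light-grey"
        # consensus W: 2/5 similar = 40% -> uncolored
        (c40,) = window_similarity(self.build("WWSGA"), [1])
        assert c40.percent == 40.0 and c40.category == "uncolored"

    def test_all_gap_column_uncolored_undefined(self):
        msa = MultipleAlignment.from_pairs([("a", "-A"), ("b", "-A")])
        (col, col2) = window_similarity(msa, [1, 2])
        assert col.percent is None and col.category == "uncolored"
        assert col2.percent == 100.0

    def test_row_order_invariance(self):
        rows = ["SA", "TA", "SG", "WG"]
        msa1 = self.build(rows)
        msa2 = self.build(list(reversed(rows)))
        r1 = [(c.percent, c.category) for c in window_similarity(msa1, [1, 2])]
        r2 = [(c.percent, c.category) for c in window_similarity(msa2, [1, 2])]
        assert r1 == r2


class TestMotifScan:
    def test_simple_match(self):
        assert motif_scan("RAAS", "R-x-x-S") == [1]

    def test_overlapping_matches(self):
        assert motif_scan("RAASRTTS", "R-x-x-S") == [1, 5]

    def test_no_match(self):
        assert motif_scan("GGGGGG", "R-x-x-S") == []

    def test_bracketed_alternatives(self):
        assert motif_scan("RAAT", "R-x-x-[ST]") == [1]

    def test_case_insensitive(self):
        assert motif_scan("raas", "R-x-x-S") == [1]

    def test_malformed_pattern(self):
        with pytest.raises(MotifError):
            motif_scan("RAAS", "R-x-x-[S")

    def test_demo_protein_carries_rxxs_at_phosphosite(self):
        from prmkit.pipeline import DEMO_SEQUENCES, DEMO_SITE_POSITION

        hits = motif_scan(DEMO_SEQUENCES["PROT1"], "R-x-x-S")
        assert DEMO_SITE_POSITION - 3 in hits
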