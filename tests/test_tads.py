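"""Insulation, boundary dynamics, domain scores, TAD pairs and cliques."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from topodyn.genome_model import ContactMatrix, IntervalSet
from topodyn.tads import (
    assign_tad_compartment,
    boundary_genes,
    call_boundaries_from_insulation,
    classify_boundary_dynamics,
    clique_gene_stats,
    domain_score,
    find_tad_cliques,
    insulation_track,
    shuffle_cliques,
    significant_tad_pairs,
    tads_from_boundaries,
)
from topodyn.genome_model import BinnedTrack

from conftest import make_genes, make_intervals, random_symmetric_counts


def brute_insulation(counts, w):
    n = counts.shape[0]
    out = np.full(n, np.nan)
    for i in range(w - 1, n - w):
        s = 0.0
        for a in range(i - w + 1, i + 1):
            for b in range(i + 1, i + w + 1):
                s += counts[a, b]
        out[i] = s
    return out


class TestInsulation:
    def test_diamond_sum_example(self):
        m = np.zeros((4, 4))
        m[0, 1] = 4
        m[2, 3] = 6
        m[0, 2] = m[0, 3] = m[1, 2] = m[1, 3] = 1
        m = m + m.T
        out = insulation_track(ContactMatrix("chr1", 10, m), 2)
        assert out[1] == pytest.approx(4.0)

    @pytest.mark.parametrize("n,w", [(20, 2), (30, 5), (25, 1), (50, 8)])
    def test_matches_brute_force(self, n, w):
        rng = np.random.default_rng(n * 10 + w)
        counts = random_symmetric_counts(rng, n)
        got = insulation_track(ContactMatrix("chr1", 10, counts), w)
        np.testing.assert_allclose(got, brute_insulation(counts, w), equal_nan=True)

    def test_all_zero_matrix(self):
        out = insulation_track(ContactMatrix("chr1", 10, np.zeros((20, 20))), 3)
        valid = np.isfinite(out)
        assert (out[valid] == 0).all()

    def test_block_diagonal_minimum_at_boundary(self):
        n = 40
        counts = np.ones((n, n)) * 0.1
        counts[:20, :20] += 5
        counts[20:, 20:] += 5
        counts = (counts + counts.T) / 2
        out = insulation_track(ContactMatrix("chr1", 10, counts), 5)
        assert np.nanargmin(out) == 19  # boundary between bins 19 and 20


class TestBoundaryCalling:
    def test_two_tad_matrix_yields_planted_boundary(self):
        n = 60
        rng = np.random.default_rng(2)
        base = 2.0 / (np.abs(np.subtract.outer(np.arange(n), np.arange(n))) + 1)
        tad = np.ones((n, n))
        tad[:30, :30] *= 3
        tad[30:, 30:] *= 3
        counts = rng.poisson(base * tad * 20).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        iv = insulation_track(ContactMatrix("chr1", 10_000, counts), 5, log_normalize=True)
        b = call_boundaries_from_insulation(iv, 0.3, "chr1", 10_000)
        positions = (b.df["start"] // 10_000).tolist()
        assert any(abs(p - 30) <= 1 for p in positions)

    def test_monotone_insulation_no_boundaries(self):
        iv = np.linspace(0, 1, 30)
        b = call_boundaries_from_insulation(iv, 0.0, "chr1", 10_000)
        assert len(b) == 0

    def test_zero_prominence_returns_all_minima(self):
        iv = np.array([3.0, 1.0, 3.0, 2.0, 3.0, 0.5, 3.0])
        b = call_boundaries_from_insulation(iv, 0.0, "chr1", 10)
        assert (b.df["start"] // 10).tolist() == [2, 4, 6]

    def test_tads_tile_chromosome(self):
        b = make_intervals([("chr1", 30, 40), ("chr1", 70, 80)])
        t = tads_from_boundaries(b, "chr1", 120)
        assert t.df[["start", "end"]].to_numpy().tolist() == [[0, 30], [30, 70], [70, 120]]


class TestBoundaryDynamics:
    def _sets(self, positions_by_tp, res=10_000):
        return {
            tp: make_intervals([("chr1", p, p + res) for p in pos])
            for tp, pos in positions_by_tp.items()
        }

    @pytest.mark.parametrize(
        "presence,label,event",
        [
            ((1, 1, 1, 1, 1), "stable", -1),
            ((0, 0, 1, 1, 1), "stably_gained", 2),
            ((1, 1, 0, 0, 0), "stably_lost", 2),
            ((1, 0, 1, 0, 1), "other", -1),
            ((0, 1, 1, 0, 1), "other", -1),
        ],
    )
    def test_presence_patterns(self, presence, label, event):
        sets = self._sets(
            {f"t{k}": ([100_000] if p else []) for k, p in enumerate(presence)}
        )
        df, _ = classify_boundary_dynamics(sets, tolerance=20_000)
        assert df.loc[0, "label"] == label
        assert df.loc[0, "event_timepoint"] == event

    def test_merging_within_tolerance(self):
        sets = self._sets({"a": [100_000], "b": [115_000]})
        df, _ = classify_boundary_dynamics(sets, tolerance=20_000)
        assert len(df) == 1 and df.loc[0, "label"] == "stable"

    def test_order_independence(self):
        sets = self._sets({"a": [100_000, 500_000], "b": [115_000], "c": [500_000]})
        df1, _ = classify_boundary_dynamics(sets, tolerance=20_000)
        reordered = {k: sets[k] for k in ["c", "a", "b"]}
        df2, _ = classify_boundary_dynamics(reordered, tolerance=20_000)
        # same merged boundaries; presence strings permuted with the input order
        assert df1["position"].tolist() == df2["position"].tolist()
        for s1, s2 in zip(df1["presence"], df2["presence"]):
            assert s1[0] == s2[1] and s1[1] == s2[2] and s1[2] == s2[0]

    def test_same_timepoint_duplicates_counted(self):
        sets = {
            "a": make_intervals([("chr1", 100_000, 110_000), ("chr1", 112_000, 122_000)]),
            "b": make_intervals([("chr1", 100_000, 110_000)]),
        }
        with pytest.warns(UserWarning, match="merged"):
            df, n_dup = classify_boundary_dynamics(sets, tolerance=20_000)
        assert n_dup == 1 and len(df) == 1


class TestBoundaryGenes:
    def test_window_is_inclusive_and_strict(self):
        genes = make_genes(
            [
                ("at", "chr1", 105_000, 115_000, "+", "protein_coding"),
                ("near", "chr1", 95_000, 99_000, "+", "protein_coding"),
                ("far", "chr1", 115_001 + 1, 130_000, "+", "protein_coding"),
            ]
        )
        # boundary midpoint at 105_000
        bounds = make_intervals([("chr1", 100_000, 110_000)])
        flags = boundary_genes(genes, bounds, tss_window=10_000)
        assert flags["at"] and flags["near"]
        assert not flags["far"]  # TSS at 115_002, distance 10_002 > 10_000

    def test_no_boundaries_on_chromosome(self):
        genes = make_genes([("g", "chr2", 0, 1000, "+", "protein_coding")])
        bounds = make_intervals([("chr1", 100_000, 110_000)])
        assert not boundary_genes(genes, bounds).any()


def brute_domain_score(counts, tad_bins, all_bins):
    scores = []
    for b in tad_bins:
        intra = sum(
            counts[i, j] for i, j in itertools.combinations(b, 2)
        )
        others = [x for bb in tad_bins for x in bb if x not in b]
        inter = sum(counts[i, j] for i in b for j in others)
        scores.append(intra / inter if inter else np.nan)
    return scores


class TestDomainScore:
    def test_worked_example(self):
        m = np.zeros((4, 4))
        m[0, 1] = 4
        m[2, 3] = 6
        m[0, 2] = m[0, 3] = m[1, 2] = m[1, 3] = 1
        m = m + m.T
        tads = make_intervals([("chr1", 0, 20), ("chr1", 20, 40)])
        out = domain_score(ContactMatrix("chr1", 10, m), tads)
        assert out["domain_score"].tolist() == [1.0, 1.5]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        n = 30
        counts = random_symmetric_counts(rng, n)
        edges = [0, 7, 15, 22, 30]
        tads = make_intervals(
            [("chr1", a * 10, b * 10) for a, b in zip(edges[:-1], edges[1:])]
        )
        out = domain_score(ContactMatrix("chr1", 10, counts), tads)
        tad_bins = [list(range(a, b)) for a, b in zip(edges[:-1], edges[1:])]
        expected = brute_domain_score(counts, tad_bins, list(range(n)))
        np.testing.assert_allclose(out["domain_score"], expected)

    def test_block_diagonal_is_missing(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 5
        m[2, 3] = m[3, 2] = 5
        tads = make_intervals([("chr1", 0, 20), ("chr1", 20, 40)])
        with pytest.warns(UserWarning, match="zero inter"):
            out = domain_score(ContactMatrix("chr1", 10, m), tads)
        assert out["domain_score"].isna().all()

    def test_subbin_tad_is_error(self):
        m = ContactMatrix("chr1", 10, np.ones((4, 4)))
        with pytest.raises(ValueError, match="smaller than one bin"):
            domain_score(m, make_intervals([("chr1", 12, 14)]))


class TestTadCompartment:
    def test_weighted_mean_labels(self):
        pc1 = BinnedTrack(10, {"chr1": np.array([1.0, 1.0, -1.0, -1.0, -1.0])})
        tads = make_intervals(
            [("chr1", 0, 20), ("chr1", 20, 50), ("chr1", 0, 40)]
        )
        out = assign_tad_compartment(tads, pc1)
        by_span = out.set_index(["start", "end"])
        assert by_span.loc[(0, 20), "compartment"] == "A"
        assert by_span.loc[(20, 50), "compartment"] == "B"
        assert by_span.loc[(0, 40), "compartment"] is None  # exact 50/50 tie

    def test_unscored_tad_unassigned(self):
        pc1 = BinnedTrack(10, {"chr1": np.array([np.nan, np.nan])})
        out = assign_tad_compartment(make_intervals([("chr1", 0, 20)]), pc1)
        assert out.loc[0, "compartment"] is None


class TestSignificantPairs:
    def _uniform_matrix(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return random_symmetric_counts(rng, n, lam=10)

    def test_needs_three_tads(self):
        m = ContactMatrix("chr1", 10, self._uniform_matrix())
        with pytest.raises(ValueError, match=">=3"):
            significant_tad_pairs(m, make_intervals([("chr1", 0, 300), ("chr1", 300, 600)]))

    def test_planted_enriched_pair_detected(self):
        n = 60
        counts = self._uniform_matrix(n, seed=4)
        # boost the (TAD0, TAD2) rectangle five-fold
        counts[0:20, 40:60] *= 5
        counts[40:60, 0:20] = counts[0:20, 40:60].T
        m = ContactMatrix("chr1", 10, counts)
        tads = make_intervals([("chr1", 0, 200), ("chr1", 200, 400), ("chr1", 400, 600)])
        out = significant_tad_pairs(m, tads, fdr=0.05)
        sig = out[out["significant"]]
        assert set(zip(sig["tad_a"], sig["tad_b"])) == {(0, 2)}

    def test_observed_equal_expected_not_significant(self):
        # a noise-free uniform matrix: every pair sits exactly at its expectation
        n = 30
        counts = np.full((n, n), 7.0)
        m = ContactMatrix("chr1", 10, counts)
        tads = make_intervals([("chr1", 0, 100), ("chr1", 100, 200), ("chr1", 200, 300)])
        out = significant_tad_pairs(m, tads)
        assert (out["p"] >= 0.5).all()
        assert not out["significant"].any()


def brute_force_cliques(edges, min_size):
    nodes = sorted({n for e in edges for n in e})
    eset = {frozenset(e) for e in edges}
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            if all(frozenset(p) in eset for p in itertools.combinations(combo, 2)):
                cliques.append(set(combo))
    return sorted(
        tuple(sorted(c)) for c in cliques
        if not any(c < other for other in cliques)
    )


class TestCliques:
    def test_complete_graph(self):
        edges = list(itertools.combinations(range(4), 2))
        assert find_tad_cliques(edges) == [(0, 1, 2, 3)]

    def test_path_graph_below_min_size(self):
        assert find_tad_cliques([(0, 1), (1, 2)], min_size=3) == []

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            edges = [
                (i, j) for i, j in itertools.combinations(range(n), 2)
                if rng.random() < 0.45
            ]
            assert find_tad_cliques(edges, min_size=3) == brute_force_cliques(edges, 3)

    def test_node_cap(self):
        edges = [(i, i + 1) for i in range(50)]
        with pytest.raises(ValueError, match="cap"):
            find_tad_cliques(edges, node_cap=10)


class TestShuffleCliques:
    def test_determinism_and_empty(self):
        cliques = [(0, 1, 2), (3, 4, 5, 6)]
        a = shuffle_cliques(cliques, list(range(10)), n=5, seed=3)
        b = shuffle_cliques(cliques, list(range(10)), n=5, seed=3)
        assert a == b
        assert shuffle_cliques(cliques, list(range(10)), n=0, seed=3) == []

    def test_sizes_preserved(self):
        cliques = [(0, 1, 2), (3, 4, 5, 6)]
        for rep in shuffle_cliques(cliques, list(range(10)), n=20, seed=1):
            assert sorted(len(c) for c in rep) == [3, 4]
            for c in rep:
                assert len(set(c)) == len(c)  # without replacement within a clique

    def test_membership_frequency_matches_hypergeometric(self):
        """A single clique of size k over N TADs includes each TAD w.p. k/N."""
        k, n_tads, reps = 3, 10, 1000
        nulls = shuffle_cliques([tuple(range(k))], list(range(n_tads)), n=reps, seed=5)
        freq = np.zeros(n_tads)
        for rep in nulls:
            for t in rep[0]:
                freq[t] += 1
        freq /= reps
        se = np.sqrt((k / n_tads) * (1 - k / n_tads) / reps)
        assert np.all(np.abs(freq - k / n_tads) < 5 * se)

    def test_oversized_clique_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            shuffle_cliques([(0, 1, 2)], [0, 1], n=1, seed=0)


class TestCliqueGeneStats:
    def test_extreme_constructions(self):
        tads = make_intervals([("chr1", i * 100, (i + 1) * 100) for i in range(6)])
        genes = make_genes(
            [(f"g{i}", "chr1", i * 100 + 10, i * 100 + 50, "+", "protein_coding")
             for i in range(6)]
        )
        cliques = [(0, 1, 2)]
        nulls = shuffle_cliques(cliques, list(range(6)), n=50, seed=0)
        inside = ["g0", "g1", "g2"]
        outside = ["g3", "g4", "g5"]
        out = clique_gene_stats(
            cliques, nulls, tads, genes, {"inside": inside, "outside": outside}
        )
        by = out.set_index("gene_set")
        assert by.loc["inside", "observed_pct"] == 100.0
        assert by.loc["outside", "observed_pct"] == 0.0
        assert 0 < by.loc["inside", "p_rank"] <= 1
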