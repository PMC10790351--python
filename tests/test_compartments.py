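"""Compartment score, trajectory labels, saddle, Mahalanobis, expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from topodyn.compartments import (
    call_compartments,
    call_compartments_bundle,
    classify_bin_trajectory,
    classify_track_trajectories,
    correlate_compartment_expression,
    de_overlap_with_switches,
    mahalanobis_change,
    observed_over_expected,
    rank_monotone_expression,
    saddle,
    switch_mass_summary,
)
from topodyn.genome_model import BinnedTrack, ContactMatrix, GeneCatalog

from conftest import make_genes, random_symmetric_counts


class TestTrajectoryLabels:
    @pytest.mark.parametrize(
        "values,label",
        [
            ([0.5, 0.4, 0.3, 0.2, 0.1], "stable_A"),
            ([-0.5, -0.4, -0.3, -0.2, -0.1], "stable_B"),
            ([0.5, 0.4, -0.3, -0.2, -0.1], "stable_AtoB"),
            ([-0.5, 0.4, 0.3, 0.2, 0.1], "stable_BtoA"),
            ([0.5, -0.4, 0.3, -0.2, 0.1], "dynamic"),
        ],
    )
    def test_sign_switch_definitions(self, values, label):
        got, _ = classify_bin_trajectory(values)
        assert got == label

    def test_switch_interval_reported(self):
        label, k = classify_bin_trajectory([0.5, 0.4, -0.3, -0.2, -0.1])
        assert label == "stable_AtoB" and k == 2

    def test_zero_carries_previous_sign(self):
        # the zero at index 2 inherits '+', so only one switch is counted
        label, k = classify_bin_trajectory([0.5, 0.4, 0.0, -0.2, -0.1])
        assert label == "stable_AtoB" and k == 3

    def test_leading_zeros_dropped(self):
        label, _ = classify_bin_trajectory([0.0, 0.0, 0.3, 0.2, 0.1])
        assert label == "stable_A"

    def test_missing_value_withholds_label(self):
        assert classify_bin_trajectory([0.5, np.nan, 0.3]) == (None, None)

    def test_all_zero_withheld(self):
        assert classify_bin_trajectory([0.0, 0.0, 0.0]) == (None, None)


class TestSwitchMass:
    def test_mb_arithmetic(self):
        labels = {"chr1": np.array(["stable_AtoB"] * 10 + ["stable_A"] * 5, dtype=object)}
        sw = {"chr1": np.array([2] * 10 + [-1] * 5)}
        summary, hist = switch_mass_summary(labels, sw, 50_000)
        atob = summary.set_index("label").loc["stable_AtoB", "mb"]
        assert atob == pytest.approx(0.5)
        assert hist.loc[2] == 10

    def test_all_stable_zero_switch_mass(self):
        labels = {"chr1": np.array(["stable_A"] * 8, dtype=object)}
        sw = {"chr1": np.full(8, -1)}
        summary, hist = switch_mass_summary(labels, sw, 50_000)
        assert summary.set_index("label").loc["stable_AtoB", "mb"] == 0
        assert hist.empty


class TestCallCompartments:
    def test_reference_flip_negates_pc1(self, small_bundle):
        tp = small_bundle.timepoints[0]
        mat = small_bundle.matrices[tp]["chr1"]
        ref = small_bundle.gene_density.values["chr1"]
        pc1 = call_compartments(mat, ref, 50_000)
        flipped = call_compartments(mat, -ref, 50_000)
        np.testing.assert_allclose(pc1, -flipped, equal_nan=True)

    def test_constant_matrix_all_missing(self):
        m = ContactMatrix("chr1", 10_000, np.ones((60, 60)))
        with pytest.warns(UserWarning):
            out = call_compartments(m, np.ones(60), None)
        assert np.isnan(out).all()

    def test_too_short_chromosome(self):
        m = ContactMatrix("chr1", 10_000, np.ones((5, 5)))
        with pytest.warns(UserWarning):
            out = call_compartments(m, np.ones(5), None)
        assert np.isnan(out).all()

    def test_planted_checkerboard_sign_agreement(self, small_bundle):
        """Called PC1 signs match the planted block pattern on >=95% of bins."""
        tp = small_bundle.timepoints[0]
        called = call_compartments_bundle(
            small_bundle.matrices[tp], small_bundle.gene_density, 50_000
        )
        agree = []
        for chrom in small_bundle.chromsizes:
            truth = np.sign(small_bundle.pc1[tp].values[chrom])
            got = called.values[chrom]
            ok = np.isfinite(got)
            agree.append(np.sign(got[ok]) == truth[ok])
        frac = np.concatenate(agree).mean()
        assert frac >= 0.95


def _brute_saddle(counts, pc1, n_quantiles, corner):
    """Independent saddle oracle: naive O/E, sorting, and corner means."""
    n = counts.shape[0]
    oe = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            d = abs(i - j)
            diag = [counts[a, a + d] for a in range(n - d)]
            m = np.mean(diag)
            if m > 0:
                oe[i, j] = counts[i, j] / m
    order = np.argsort(pc1, kind="stable")
    groups = np.array_split(order, n_quantiles)
    s = np.zeros((n_quantiles, n_quantiles))
    for a in range(n_quantiles):
        for b in range(n_quantiles):
            vals = [oe[i, j] for i in groups[a] for j in groups[b] if np.isfinite(oe[i, j])]
            s[a, b] = np.mean(vals)
    c = corner
    return (
        np.nanmean(s[-c:, -c:]),
        np.nanmean(s[:c, :c]),
        np.mean([np.nanmean(s[:c, -c:]), np.nanmean(s[-c:, :c])]),
    )


class TestSaddle:
    def test_uniform_oe_gives_unit_strengths(self):
        n = 64
        decay = 1.0 / (np.abs(np.subtract.outer(np.arange(n), np.arange(n))) + 1)
        m = ContactMatrix("chr1", 10_000, decay)
        res = saddle(m, np.linspace(-1, 1, n), n_quantiles=8, corner=2)
        np.testing.assert_allclose(res.matrix, 1.0, atol=1e-12)
        assert res.aa == pytest.approx(1.0) and res.bb == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        counts = random_symmetric_counts(rng, 40, lam=20)
        pc1 = rng.normal(size=40)
        m = ContactMatrix("chr1", 10_000, counts)
        res = saddle(m, pc1, n_quantiles=8, corner=2)
        aa, bb, ab = _brute_saddle(counts, pc1, 8, 2)
        assert res.aa == pytest.approx(aa, abs=1e-10)
        assert res.bb == pytest.approx(bb, abs=1e-10)
        assert res.ab == pytest.approx(ab, abs=1e-10)

    def test_permuted_pc1_destroys_sorting(self, small_bundle):
        tp = small_bundle.timepoints[0]
        mat = small_bundle.matrices[tp]["chr1"].rebin(50_000)
        pc1 = small_bundle.pc1[tp].values["chr1"]
        rng = np.random.default_rng(0)
        res = saddle(mat, rng.permutation(pc1), n_quantiles=20, corner=4)
        assert abs(res.aa - 1) < 0.15 and abs(res.bb - 1) < 0.15

    def test_sign_flip_swaps_corners(self):
        rng = np.random.default_rng(6)
        counts = random_symmetric_counts(rng, 40, lam=20)
        pc1 = rng.normal(size=40)
        m = ContactMatrix("chr1", 10_000, counts)
        a = saddle(m, pc1, n_quantiles=8, corner=2)
        b = saddle(m, -pc1, n_quantiles=8, corner=2)
        assert a.aa == pytest.approx(b.bb, abs=1e-9)
        assert a.bb == pytest.approx(b.aa, abs=1e-9)


class TestMahalanobis:
    def test_matches_linear_algebra_oracle(self):
        vals = np.array(
            [[0.2, -0.1], [1.0, 0.8], [-0.5, -0.7], [0.3, 0.9], [-1.2, -1.0], [0.0, 0.1]]
        )
        tracks = [
            BinnedTrack(50_000, {"chr1": vals[:, t]}, {"chr1": 300_000}) for t in range(2)
        ]
        md, flags = mahalanobis_change(tracks)
        mu = vals.mean(axis=0)
        sigma = np.cov(vals, rowvar=False)
        sigma += np.eye(2) * (1e-8 * np.trace(sigma) / 2)
        inv = np.linalg.inv(sigma)
        ref = np.sqrt(np.einsum("ij,jk,ik->i", vals - mu, inv, vals - mu))
        np.testing.assert_allclose(md.values["chr1"], ref, atol=1e-9)
        assert flags["chr1"].tolist() == (ref > 1).tolist()

    def test_bin_at_mean_has_zero_distance(self):
        vals = np.array([[1.0, 2.0], [-1.0, -2.0], [0.0, 0.0], [2.0, 1.0], [-2.0, -1.0]])
        tracks = [
            BinnedTrack(50_000, {"chr1": vals[:, t]}, {"chr1": 250_000}) for t in range(2)
        ]
        md, _ = mahalanobis_change(tracks)
        assert md.values["chr1"][2] == pytest.approx(0.0, abs=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(40, 3))
        tracks = [
            BinnedTrack(50_000, {"chr1": vals[:, t]}, {"chr1": 2_000_000}) for t in range(3)
        ]
        md1, _ = mahalanobis_change(tracks)
        vals2 = vals.copy()
        vals2[:, 1] = 3.5 * vals2[:, 1] - 2.0
        tracks2 = [
            BinnedTrack(50_000, {"chr1": vals2[:, t]}, {"chr1": 2_000_000}) for t in range(3)
        ]
        md2, _ = mahalanobis_change(tracks2)
        np.testing.assert_allclose(md1.values["chr1"], md2.values["chr1"], atol=1e-6)

    def test_missing_bins_excluded(self):
        v0 = np.array([1.0, np.nan, 2.0, -1.0, 0.5])
        v1 = np.array([0.5, 1.0, -2.0, 1.0, 0.2])
        tracks = [
            BinnedTrack(50_000, {"chr1": v}, {"chr1": 250_000}) for v in (v0, v1)
        ]
        md, _ = mahalanobis_change(tracks)
        assert np.isnan(md.values["chr1"][1])
        assert np.isfinite(md.values["chr1"][[0, 2, 3, 4]]).all()


class TestExpressionCoupling:
    def _setup(self):
        genes = make_genes(
            [(f"g{i}", "chr1", i * 100_000, i * 100_000 + 10_000, "+", "protein_coding")
             for i in range(12)]
        )
        res = 50_000
        n = 24
        return genes, res, n

    def test_perfect_coupling_gives_r_one(self):
        genes, res, n = self._setup()
        rng = np.random.default_rng(0)
        v0 = rng.normal(size=n)
        v1 = v0 + rng.normal(size=n)
        tracks = {
            "t0": BinnedTrack(res, {"chr1": v0}),
            "t1": BinnedTrack(res, {"chr1": v1}),
        }
        dpc1 = {g: v1[(i * 2)] - v0[(i * 2)] for i, g in enumerate(genes.df["id"])}
        # expression change constructed to match delta-PC1 exactly
        expr = pd.DataFrame(
            {
                "t0_1": [1.0] * 12,
                "t1_1": [2 ** (np.log2(2.0) + dpc1[g]) - 1 for g in genes.df["id"]],
            },
            index=genes.df["id"],
        )
        r, p, n_used, dropped = correlate_compartment_expression(
            tracks, expr, genes, genes.df["id"], "t0", "t1"
        )
        assert r == pytest.approx(1.0)
        assert n_used == 12 and dropped == 0

    def test_small_gene_set_is_error(self):
        genes, res, n = self._setup()
        tracks = {
            "t0": BinnedTrack(res, {"chr1": np.ones(n)}),
            "t1": BinnedTrack(res, {"chr1": np.ones(n)}),
        }
        expr = pd.DataFrame({"t0_1": [1.0] * 3, "t1_1": [1.0] * 3}, index=["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="need >=10"):
            correlate_compartment_expression(tracks, expr, genes, ["g0", "g1", "g2"], "t0", "t1")


class TestRankMonotone:
    def test_monotone_eligibility_and_ratio(self):
        expr = pd.DataFrame(
            {
                "A_1": [1.0, 1.0],
                "B_1": [2.0, 3.0],
                "C_1": [3.0, 2.0],
                "D_1": [4.0, 4.0],
                "E_1": [8.0, 8.0],
            },
            index=["mono", "dip"],
        )
        top, bottom = rank_monotone_expression(expr, ["A", "B", "C", "D", "E"], frac=0.5)
        assert "mono" in top and "dip" not in top + bottom

    def test_decile_counts(self):
        rng = np.random.default_rng(1)
        base = np.sort(rng.uniform(1, 10, size=(100, 4)), axis=1)
        expr = pd.DataFrame(base, columns=["A_1", "B_1", "C_1", "D_1"],
                            index=[f"g{i}" for i in range(100)])
        top, bottom = rank_monotone_expression(expr, ["A", "B", "C", "D"])
        assert len(top) == 10 and len(bottom) == 10

    def test_no_monotone_genes_warns(self):
        expr = pd.DataFrame(
            {"A_1": [1.0], "B_1": [3.0], "C_1": [2.0], "D_1": [4.0]}, index=["g"]
        )
        with pytest.warns(UserWarning):
            top, bottom = rank_monotone_expression(expr, ["A", "B", "C", "D"])
        assert top == [] and bottom == []


class TestDeOverlap:
    def test_constructed_placement(self):
        genes = make_genes(
            [("up1", "chr1", 0, 10_000, "+", "protein_coding"),
             ("up2", "chr1", 55_000, 60_000, "+", "protein_coding"),
             ("dn1", "chr1", 100_000, 110_000, "+", "protein_coding")]
        )
        labels = {"chr1": np.array(["stable_BtoA", "stable_BtoA", "stable_AtoB"], dtype=object)}
        counts = de_overlap_with_switches(["up1", "up2"], ["dn1"], labels, genes, 50_000)
        assert counts.loc["stable_BtoA", "up"] == 2
        assert counts.loc["stable_AtoB", "down"] == 1
        assert counts.loc["stable_A"].sum() == 0

    def test_empty_de_lists(self):
        genes = make_genes([("g", "chr1", 0, 1000, "+", "protein_coding")])
        labels = {"chr1": np.array(["stable_A"], dtype=object)}
        counts = de_overlap_with_switches([], [], labels, genes, 50_000)
        assert counts.to_numpy().sum() == 0
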