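"""Composition transforms, ordination, and permutation tests."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from drillcore import (
    CommunityMatrix,
    CoreDataset,
    DegenerateDataError,
    DissimilarityMatrix,
    ValidationError,
    bray_curtis,
    dbrda,
    df_by_unit_tests,
    nmds,
    pcoa,
    permanova,
    sqrt_transform,
    to_proportions,
)

from conftest import bivalve_row, gastropod_row, make_increment


def dissim_from_points(points):
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return DissimilarityMatrix(ids=tuple(f"s{i}" for i in range(n)), values=d)


class TestProportions:
    def test_even_counts(self):
        ds = CoreDataset(
            increments=[make_increment("i0", 0, 2)],
            counts=[
                gastropod_row("i0", taxon="a", n_whole=2),
                gastropod_row("i0", taxon="b", n_whole=2),
            ],
        )
        cm = to_proportions(ds)
        assert cm.data.loc["i0"].tolist() == [0.5, 0.5]

    def test_single_taxon_row(self):
        ds = CoreDataset(
            increments=[make_increment("i0", 0, 2)],
            counts=[gastropod_row("i0", n_whole=7)],
        )
        assert to_proportions(ds).data.loc["i0"].tolist() == [1.0]

    def test_valve_correction_in_proportions(self):
        # bivalve RV=2 LV=2 A=1 -> 3 individuals, plus 7 gastropod shells
        ds = CoreDataset(
            increments=[make_increment("i0", 0, 2)],
            counts=[
                bivalve_row("i0", n_right=2, n_left=2, n_articulated=1),
                gastropod_row("i0", n_whole=7),
            ],
        )
        row = to_proportions(ds).data.loc["i0"]
        assert sorted(row.tolist()) == pytest.approx([0.3, 0.7])

    def test_empty_increment_excluded(self):
        ds = CoreDataset(
            increments=[make_increment("i0", 0, 2), make_increment("i1", 2, 4)],
            counts=[gastropod_row("i0", n_whole=5)],
        )
        assert list(to_proportions(ds).data.index) == ["i0"]

    def test_rows_sum_to_one(self, two_increment_dataset):
        cm = to_proportions(two_increment_dataset)
        assert cm.data.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])


class TestTransformAndBrayCurtis:
    @pytest.mark.parametrize("value,expected", [(0.25, 0.5), (0.0, 0.0), (1.0, 1.0)])
    def test_sqrt(self, value, expected):
        cm = CommunityMatrix(pd.DataFrame({"t": [value]}, index=["s"]))
        assert sqrt_transform(cm).data.iloc[0, 0] == expected

    def test_sqrt_rejects_negative(self):
        cm = CommunityMatrix(pd.DataFrame({"t": [-0.1]}, index=["s"]))
        with pytest.raises(ValidationError):
            sqrt_transform(cm)

    def test_identical_rows_zero(self):
        cm = CommunityMatrix(pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"]))
        assert bray_curtis(cm).values[0, 1] == 0.0

    def test_disjoint_support_one(self):
        cm = CommunityMatrix(pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"]))
        assert bray_curtis(cm).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value_after_sqrt(self):
        """sqrt of (1,0) and (0.5,0.5): d = 1 - 2*sqrt(0.5)/(1 + 2*sqrt(0.5))."""
        cm = sqrt_transform(
            CommunityMatrix(pd.DataFrame([[1.0, 0.0], [0.5, 0.5]], index=["a", "b"]))
        )
        r = np.sqrt(0.5)
        expected = 1 - 2 * r / (1 + 2 * r)
        assert bray_curtis(cm).values[0, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4142, abs=1e-4)

    def test_column_order_invariance(self):
        frame = pd.DataFrame([[0.2, 0.3, 0.5], [0.6, 0.1, 0.3]], index=["a", "b"],
                             columns=["x", "y", "z"])
        d1 = bray_curtis(CommunityMatrix(frame))
        d2 = bray_curtis(CommunityMatrix(frame[["z", "x", "y"]]))
        assert np.allclose(d1.values, d2.values)

    def test_all_zero_row_rejected(self):
        cm = CommunityMatrix(pd.DataFrame([[0.0, 0.0], [0.5, 0.5]], index=["a", "b"]))
        with pytest.raises(DegenerateDataError):
            bray_curtis(cm)


class TestNMDS:
    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(10, 2))
        result = nmds(dissim_from_points(points), k=2, seed=1)
        assert result.stress < 0.01

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            nmds(dissim_from_points(np.eye(3)[:, :2] * 2), k=2)

    def test_deterministic_canonical_coordinates(self):
        rng = np.random.default_rng(5)
        d = dissim_from_points(rng.normal(size=(8, 2)))
        a = nmds(d, seed=7)
        b = nmds(d, seed=7)
        assert np.allclose(a.coordinates.values, b.coordinates.values)
        assert a.stress == b.stress

    def test_best_stress_not_worse_than_metric_start(self):
        rng = np.random.default_rng(9)
        # noisy high-dimensional composition: metric start is good but
        # improvable; the reported stress can only be at least as good
        comp = rng.dirichlet(np.ones(6), size=12)
        cm = sqrt_transform(CommunityMatrix(pd.DataFrame(comp, index=[f"s{i}" for i in range(12)])))
        d = bray_curtis(cm)
        from sklearn.manifold import MDS

        from drillcore.community_stats import _MDS_METRIC_KW

        metric_init = pcoa(d).coordinates[:, :2]
        model = MDS(n_components=2, dissimilarity="precomputed",
                    n_init=1, max_iter=300, eps=1e-9, normalized_stress=True,
                    **{_MDS_METRIC_KW: False})
        model.fit(d.values, init=metric_init)
        assert nmds(d, seed=2).stress <= model.stress_ + 1e-12


def permanova_F_oracle(d, labels):
    """Independent pseudo-F via explicit group sums of squared distances."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_t = (d**2).sum() / (2 * n)
    ss_w = 0.0
    for g in set(labels.tolist()):
        idx = np.flatnonzero(labels == g)
        sub = d[np.ix_(idx, idx)]
        ss_w += (sub**2).sum() / (2 * len(idx))
    a = len(set(labels.tolist()))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    @pytest.fixture
    def six_sample_dissim(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(6, 3))
        pts[:3] += 1.5
        return dissim_from_points(pts)

    def test_exact_p_matches_enumeration(self, six_sample_dissim):
        labels = ["a", "a", "a", "b", "b", "b"]
        result = permanova(six_sample_dissim, labels, exact=True)
        d = six_sample_dissim.values
        F_obs = permanova_F_oracle(d, labels)
        count = 0
        arrangements = list(
            set(itertools.permutations(labels))
        )  # 20 distinct label arrangements
        for arr in arrangements:
            count += permanova_F_oracle(d, list(arr)) >= F_obs - 1e-12
        assert result.p_perm == pytest.approx(count / len(arrangements))
        assert result.pseudo_F == pytest.approx(F_obs)

    def test_single_group_rejected(self, six_sample_dissim):
        with pytest.raises(DegenerateDataError):
            permanova(six_sample_dissim, ["a"] * 6)

    def test_group_of_one_rejected(self, six_sample_dissim):
        with pytest.raises(DegenerateDataError):
            permanova(six_sample_dissim, ["a", "b", "b", "b", "b", "b"])

    def test_relabelling_invariance(self, six_sample_dissim):
        a = permanova(six_sample_dissim, ["a", "a", "a", "b", "b", "b"], n_perm=199, seed=1)
        b = permanova(six_sample_dissim, ["x", "x", "x", "y", "y", "y"], n_perm=199, seed=1)
        assert a.pseudo_F == pytest.approx(b.pseudo_F)
        assert a.p_perm == b.p_perm

    def test_pseudo_F_matches_scikit_bio(self):
        """Cross-check the statistic against the reference implementation."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(9, 4))
        d = dissim_from_points(pts)
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        ours = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.values, ids=list(d.ids)),
            grouping=labels,
            permutations=99,
        )
        assert ours.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_strata_restrict_permutations(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        d = dissim_from_points(pts)
        labels = ["a", "a", "b", "b", "a", "a", "b", "b"]
        strata = ["s1"] * 4 + ["s2"] * 4
        result = permanova(d, labels, n_perm=199, seed=5, strata=strata)
        assert 0 < result.p_perm <= 1


class TestDFByUnit:
    def test_hand_derived_H(self):
        """Groups {1,2},{3,4},{5,6}: rank means 1.5/3.5/5.5 -> H = 32/7."""
        result = df_by_unit_tests({"u1": [1, 2], "u2": [3, 4], "u3": [5, 6]})
        assert result.h_statistic == pytest.approx(32 / 7, abs=1e-3)
        assert result.h_statistic == pytest.approx(4.571, abs=1e-3)
        assert result.dof == 2

    def test_identical_values_H_zero(self):
        result = df_by_unit_tests({"u1": [2, 2], "u2": [2, 2]})
        assert result.h_statistic == 0.0
        assert result.p_value == 1.0

    def test_two_groups_bonferroni_factor_one(self):
        from scipy.stats import mannwhitneyu

        a, b = [0.1, 0.3, 0.2], [0.5, 0.6, 0.4]
        result = df_by_unit_tests({"u1": a, "u2": b})
        raw = mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert result.pairwise[("u1", "u2")] == pytest.approx(raw)

    def test_small_units_dropped(self):
        result = df_by_unit_tests({"u1": [1, 2, 3], "u2": [4, 5], "u3": [9]})
        assert result.dropped == ("u3",)
        with pytest.raises(DegenerateDataError):
            df_by_unit_tests({"u1": [1, 2], "u2": [3]})


class TestDbRDA:
    def test_self_constraint_recovers_first_axis(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(10, 3)) * np.array([3.0, 1.0, 0.5])
        d = dissim_from_points(pts)
        pc = pcoa(d)
        result = dbrda(d, pc.coordinates[:, 0], n_perm=999, seed=0)
        expected = pc.eigenvalues[0] / pc.eigenvalues.sum()
        assert result.constrained_fraction == pytest.approx(expected, rel=1e-9)
        assert result.p_perm <= 0.05

    def test_three_samples_rejected(self):
        d = dissim_from_points(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValidationError):
            dbrda(d, [1.0, 2.0, 3.0])

    def test_constant_constraint_rejected(self):
        d = dissim_from_points(np.random.default_rng(0).normal(size=(6, 2)))
        with pytest.raises(DegenerateDataError):
            dbrda(d, [1.0] * 6)


def test_pcoa_reproduces_euclidean_geometry():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(7, 2))
    pc = pcoa(dissim_from_points(pts))
    # pairwise distances of the PCoA configuration equal the input
    rec = np.sqrt(((pc.coordinates[:, None] - pc.coordinates[None]) ** 2).sum(-1))
    d = dissim_from_points(pts).values
    assert np.allclose(rec, d, atol=1e-8)
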