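"""Evidence binning, Gower distance, Ward clustering, Fisher summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from cpma.cluster import (
    DistanceMatrix,
    EvidenceMatrix,
    bin_evidence,
    cluster_disease_summary,
    cut_clusters,
    evidence_matrix,
    gower_distance,
    to_newick,
    ward_linkage,
)
from cpma.core import AssociationCell, AssociationMatrix, SnpRecord


def _em(rows, snp_ids=None, phenos=None):
    arr = np.asarray(rows, dtype=float)
    snp_ids = snp_ids or [f"s{i:02d}" for i in range(arr.shape[0])]
    phenos = phenos or [f"d{j}" for j in range(arr.shape[1])]
    return EvidenceMatrix(frame=pd.DataFrame(arr, index=snp_ids, columns=phenos))


class TestBinning:
    @pytest.mark.parametrize(
        "p, cls",
        [
            (0.5, 0), (1.0, 0), (0.05, 0),        # boundary to weaker bin
            (0.049, 1), (0.001, 1),
            (9.9e-4, 2), (1e-6, 2),
            (9.9e-7, 3), (1e-8, 3), (1e-300, 3),
        ],
    )
    def test_cutpoints(self, p, cls):
        assert bin_evidence(p) == cls

    def test_missing_propagates(self):
        assert bin_evidence(None) is None
        assert bin_evidence(float("nan")) is None

    def test_domain(self):
        with pytest.raises(ValueError):
            bin_evidence(0.0)
        with pytest.raises(ValueError):
            bin_evidence(1.5)

    @given(st.floats(min_value=1e-300, max_value=1.0),
           st.floats(min_value=1e-300, max_value=1.0))
    def test_monotone_step_function(self, p1, p2):
        # smaller p never gets a weaker class
        if p1 <= p2:
            assert bin_evidence(p1) >= bin_evidence(p2)

    def test_fixture_binning_has_expected_shape(self, table2):
        em = evidence_matrix(table2)
        assert em.frame.shape == (47, 7)
        assert int(em.frame.isna().sum().sum()) == 1  # rs2082412 MS


class TestGower:
    def test_identical_profiles(self):
        em = _em([[0, 1, 2, 3, 0, 1, 2], [0, 1, 2, 3, 0, 1, 2]])
        assert gower_distance(em).d[0, 1] == 0.0

    def test_mismatch_fraction(self):
        em = _em([[0, 0, 0, 0, 0, 0, 0], [1, 2, 3, 0, 0, 0, 0]])
        assert gower_distance(em).d[0, 1] == pytest.approx(3 / 7)

    def test_missing_uses_shared_phenotypes_only(self):
        em = _em([[0, 1, 2, 3, 0, 1, np.nan], [0, 1, 2, 3, 0, 1, 2]])
        assert gower_distance(em).d[0, 1] == 0.0

    def test_ordinal_mode_scales_by_rank_gap(self):
        em = _em([[0, 0], [3, 1]])
        d = gower_distance(em, mode="ordinal").d[0, 1]
        assert d == pytest.approx((3 / 3 + 1 / 3) / 2)

    def test_all_missing_row_rejected(self):
        em = _em([[np.nan, np.nan], [0, 1]])
        with pytest.raises(ValueError, match="all-missing"):
            gower_distance(em)

    def test_no_shared_phenotype_rejected(self):
        em = _em([[0, np.nan], [np.nan, 1]])
        with pytest.raises(ValueError, match="no shared"):
            gower_distance(em)

    def test_metric_sanity_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n, m = rng.integers(2, 8), rng.integers(1, 9)
            em = _em(rng.integers(0, 4, size=(n, m)))
            for mode in ("categorical", "ordinal"):
                d = gower_distance(em, mode=mode).d
                assert np.allclose(d, d.T)
                assert np.all(np.diag(d) == 0.0)
                assert np.all((d >= 0.0) & (d <= 1.0 + 1e-12))


class TestWard:
    def test_two_items(self):
        dm = DistanceMatrix(labels=["a", "b"], d=np.array([[0, 0.7], [0.7, 0]]))
        tree = ward_linkage(dm)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.7)

    def test_separated_groups_merge_within_first(self):
        # 6 points, 2 groups: within-group distance 0, between-group 1
        labels = [f"p{i}" for i in range(6)]
        d = np.ones((6, 6))
        np.fill_diagonal(d, 0.0)
        d[np.ix_([0, 1, 2], [0, 1, 2])] = 0.0
        d[np.ix_([3, 4, 5], [3, 4, 5])] = 0.0
        np.fill_diagonal(d, 0.0)
        tree = ward_linkage(DistanceMatrix(labels=labels, d=d))
        # first four merges are the zero-cost within-group ones
        assert np.all(tree.merges[:4, 2] == 0.0)
        model = cut_clusters(tree, k=2)
        assert model.partition() == {
            frozenset({"p0", "p1", "p2"}), frozenset({"p3", "p4", "p5"})
        }

    def test_label_invariance_under_input_permutation(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 4, size=(12, 5))
        em1 = _em(base)
        order = rng.permutation(12)
        em2 = _em(base[order], snp_ids=[f"s{i:02d}" for i in order])
        for k in (2, 3, 5):
            m1 = cut_clusters(ward_linkage(gower_distance(em1)), k=k)
            m2 = cut_clusters(ward_linkage(gower_distance(em2)), k=k)
            assert m1.partition() == m2.partition()

    def test_cut_refinement_chain(self, table2):
        from cpma.cluster import evidence_matrix

        tree = ward_linkage(gower_distance(evidence_matrix(table2)))
        prev = None
        for k in range(1, 12):
            part = cut_clusters(tree, k=k).partition()
            assert len(part) == k
            if prev is not None:
                # k-cluster partition refines the (k-1)-cluster one
                for cl in part:
                    assert any(cl <= big for big in prev)
            prev = part

    def test_cut_extremes(self):
        em = _em(np.arange(8).reshape(4, 2) % 4)
        tree = ward_linkage(gower_distance(em))
        assert len(cut_clusters(tree, k=4).partition()) == 4
        assert len(cut_clusters(tree, k=1).partition()) == 1
        with pytest.raises(ValueError):
            cut_clusters(tree, k=0)
        with pytest.raises(ValueError):
            cut_clusters(tree, k=5)

    def test_ward_d2_matches_scipy_on_tie_free_data(self):
        # independent oracle: scipy's ward linkage on euclidean distances
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(15, 3))
        d = squareform(pdist(pts))
        labels = [f"x{i:02d}" for i in range(15)]
        tree = ward_linkage(DistanceMatrix(labels=labels, d=d), dialect="ward_d2")
        z = linkage(pdist(pts), method="ward")
        for k in (2, 3, 4, 6):
            mine = cut_clusters(tree, k=k).partition()
            flat = fcluster(z, t=k, criterion="maxclust")
            theirs = {
                frozenset(labels[i] for i in np.flatnonzero(flat == c))
                for c in np.unique(flat)
            }
            assert mine == theirs

    def test_heights_nondecreasing(self, table2):
        for dialect in ("ward_d", "ward_d2"):
            tree = ward_linkage(
                gower_distance(evidence_matrix(table2)), dialect=dialect
            )
            h = tree.merges[:, 2]
            assert np.all(np.diff(h) >= -1e-12)

    def test_fixture_partition_is_deterministic(self, table2):
        runs = [
            cut_clusters(
                ward_linkage(gower_distance(evidence_matrix(table2))), k=4
            ).partition()
            for _ in range(3)
        ]
        assert runs[0] == runs[1] == runs[2]

    def test_newick_roundtrip_topology(self):
        em = _em([[0, 0], [0, 1], [3, 3], [3, 2]],
                 snp_ids=["a", "b", "c", "d"])
        tree = ward_linkage(gower_distance(em))
        nwk = to_newick(tree)
        assert nwk.endswith(";")
        for name in "abcd":
            assert name in nwk


class TestClusterSummary:
    def _matrix(self, pvals, phenos):
        records = []
        for i, row in enumerate(pvals):
            cells = {
                ph: AssociationCell() if p is None
                else AssociationCell(z=1.0, p=p)
                for ph, p in zip(phenos, row)
            }
            records.append(SnpRecord(snp_id=f"s{i}", cells=cells))
        return AssociationMatrix(phenotypes=list(phenos), records=records)

    def test_singleton_cluster_is_fisher_identity(self):
        from cpma.cluster import ClusterModel

        am = self._matrix([[0.37, 0.8]], ["d1", "d2"])
        model = ClusterModel(tree=None, k=1, assignment={"s0": 1})
        out = cluster_disease_summary(model, am).set_index("phenotype")
        assert out.loc["d1", "combined_p"] == pytest.approx(0.37, rel=1e-10)
        assert out.loc["d2", "combined_p"] == pytest.approx(0.8, rel=1e-10)

    def test_three_member_cluster(self):
        from cpma.cluster import ClusterModel

        am = self._matrix([[0.01], [0.02], [0.03]], ["d1"])
        model = ClusterModel(
            tree=None, k=1, assignment={"s0": 1, "s1": 1, "s2": 1}
        )
        out = cluster_disease_summary(model, am)
        row = out.iloc[0]
        expect = -2 * (math.log(0.01) + math.log(0.02) + math.log(0.03))
        assert row["s_cum"] == pytest.approx(expect, rel=1e-10)
        assert row["df"] == 6
        # frozen from the chi-square(6) tail oracle
        assert row["combined_p"] == pytest.approx(5.1185e-4, rel=1e-3)

    def test_empty_phenotype_column_is_undefined(self):
        from cpma.cluster import ClusterModel

        am = self._matrix([[0.5, None], [0.6, None]], ["d1", "d2"])
        model = ClusterModel(tree=None, k=1, assignment={"s0": 1, "s1": 1})
        out = cluster_disease_summary(model, am).set_index("phenotype")
        assert np.isnan(out.loc["d2", "combined_p"])
        assert out.loc["d2", "n"] == 0
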