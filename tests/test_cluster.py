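import subprocess
import textwrap

import numpy as np
import pytest

from cncohort.cluster import (
    Dendrogram,
    build_heatmap,
    linkage_from_distances,
    ward_linkage,
)
from cncohort.genome import GenomeBuild, make_windows
from cncohort.io import CopyNumberSegment, PloidyTable, SampleTable, SegmentSet
from cncohort.matrix import build_matrix, to_relative

from _oracles import ward_d_agglomerate


class TestWardLinkage:
    def test_lance_williams_worked_example(self):
        # 1-D profiles 0, 1, 10: first merge at 1, then (2*10+2*9-1)/3
        d = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        (a0, b0, h0), (a1, b1, h1) = d.merges
        assert (a0, b0) == (0, 1) and h0 == pytest.approx(1.0)
        assert (a1, b1) == (2, 3)
        assert h1 == pytest.approx(37 / 3)

    def test_identical_profiles_merge_at_zero(self):
        d = ward_linkage(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.merges[0][2] == 0.0

    def test_permutation_leaves_heights_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 5))
        h1 = sorted(h for _, _, h in ward_linkage(X).merges)
        perm = rng.permutation(7)
        h2 = sorted(h for _, _, h in ward_linkage(X[perm]).merges)
        assert np.allclose(h1, h2)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ward_linkage(np.array([[1.0]]))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        X = rng.integers(0, 5, size=(n, int(rng.integers(1, 7)))).astype(float)
        d = ward_linkage(X)
        oracle = ward_d_agglomerate(X)
        sizes = {i: frozenset([i]) for i in range(n)}
        for t, ((a, b, h), (oa, ob, oh)) in enumerate(zip(d.merges, oracle)):
            la, lb = sizes[a], sizes[b]
            sizes[n + t] = la | lb
            assert {la, lb} == {oa, ob}
            assert h == pytest.approx(oh, abs=1e-9, rel=1e-9)

    def test_columns_mode_clusters_windows(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 6))
        d = ward_linkage(X, on="columns")
        assert d.n_leaves == 6

    def test_other_methods_run(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        for method in ("ward.D2", "average", "complete", "single"):
            d = ward_linkage(X, method=method)
            assert len(d.merges) == 4

    def test_agrees_with_r_hclust_ward_d(self, tmp_path):
        """Independent cross-check against R's hclust(method='ward.D')."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(9, 6))
        mat = tmp_path / "m.tsv"
        np.savetxt(mat, X, delimiter="\t")
        script = tmp_path / "h.R"
        script.write_text(
            textwrap.dedent(
                f"""
                m <- as.matrix(read.table("{mat}", sep="\\t"))
                h <- hclust(dist(m), method="ward.D")
                cat(h$height, sep="\\n")
                """
            )
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        r_heights = sorted(float(x) for x in res.stdout.split())
        py_heights = sorted(h for _, _, h in ward_linkage(X).merges)
        assert np.allclose(py_heights, r_heights, rtol=1e-6)


class TestDendrogramStructure:
    def test_linkage_matrix_and_leaf_order(self):
        d = ward_linkage(np.array([[0.0], [1.0], [10.0]]), labels=["a", "b", "c"])
        Z = d.to_linkage()
        assert Z.shape == (2, 4)
        assert Z[-1, 3] == 3
        assert sorted(d.leaf_order) == [0, 1, 2]

    def test_newick_contains_all_labels(self):
        d = ward_linkage(
            np.array([[0.0], [1.0], [10.0], [11.0]]),
            labels=["s1", "s2", "s3", "s4"],
        )
        nwk = d.to_newick()
        for lab in ("s1", "s2", "s3", "s4"):
            assert lab in nwk
        assert nwk.endswith(";")


def _toy_matrix():
    b = GenomeBuild("t", (("c1", 300),))
    ws = make_windows(b, size=100)
    segs = [
        CopyNumberSegment("S1", "c1", 0, 300, 1, 1),
        CopyNumberSegment("S2", "c1", 0, 300, 3, 1),
        CopyNumberSegment("S3", "c1", 0, 300, 1, 1),
    ]
    pt = PloidyTable({"S1": 2, "S2": 2, "S3": 2})
    return build_matrix(SegmentSet.from_iterable(segs), ws, ploidies=pt), pt


class TestHeatmap:
    def test_values_passthrough_under_permutation(self):
        m, _ = _toy_matrix()
        layout = build_heatmap(m)
        assert layout.col_order == (0, 1, 2)  # genomic order kept
        for r, si in enumerate(layout.row_order):
            assert (layout.values[r] == m.values[si]).all()

    def test_cluster_windows_permutes_columns(self):
        m, _ = _toy_matrix()
        layout = build_heatmap(m, cluster_windows=True)
        assert sorted(layout.col_order) == [0, 1, 2]
        assert layout.col_dendrogram is not None

    def test_one_layout_per_feature(self):
        import pandas as pd

        m, _ = _toy_matrix()
        st = SampleTable(
            pd.DataFrame(
                {"Sample": ["S1", "S2", "S3"], "BCLC": ["A", "B", "A"],
                 "Grade": ["1", "2", "2"]}
            )
        )
        layouts = build_heatmap(m, sample_table=st)
        assert [l.feature for l in layouts] == ["BCLC", "Grade"]
        assert layouts[0].feature_values is not None

    def test_unknown_feature_rejected(self):
        import pandas as pd

        m, _ = _toy_matrix()
        st = SampleTable(pd.DataFrame({"Sample": ["S1"], "BCLC": ["A"]}))
        with pytest.raises(KeyError, match="unknown feature"):
            build_heatmap(m, sample_table=st, feature="nope")

    def test_absolute_and_relative_agree_at_shared_ploidy(self):
        m, pt = _toy_matrix()
        rel = to_relative(m, pt)
        ha = ward_linkage(m, on="rows")
        hr = ward_linkage(rel, on="rows")
        assert [(a, b) for a, b, _ in ha.merges] == [(a, b) for a, b, _ in hr.merges]
        assert np.allclose(ha.heights, hr.heights)
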