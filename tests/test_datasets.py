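import numpy as np
import pandas as pd
import pytest

from cohex.datasets import (
    DatasetError,
    ExpressionMatrix,
    FunctionalCategorySet,
    combine_datasets,
    compute_fold_changes,
    dataset_homogeneity,
    filter_by_evidence,
    read_expression,
    read_gene_sets,
    write_expression,
    write_gene_sets,
)


def _matrix(values, genes=None, samples=None, kind="intensity"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), kind)


class TestExpressionIO:
    def test_round_trip_identity(self, tmp_path):
        expr = _matrix(np.random.default_rng(0).standard_normal((3, 3)))
        path = tmp_path / "x.tsv"
        write_expression(expr, path)
        back = read_expression(path)
        np.testing.assert_allclose(back.to_array(), expr.to_array(), rtol=1e-9)
        assert back.gene_ids == expr.gene_ids
        assert back.sample_ids == expr.sample_ids

    def test_meta_sidecar_round_trip(self, tmp_path):
        expr = _matrix(np.ones((2, 3)), kind="fold_change")
        write_expression(expr, tmp_path / "x.tsv", tmp_path / "m.tsv")
        back = read_expression(tmp_path / "x.tsv", meta_path=tmp_path / "m.tsv")
        assert back.value_kind == "fold_change"
        assert list(back.sample_meta.columns) == ["dataset", "condition", "role"]

    def test_duplicate_gene_errors_with_name(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\ts1\ts2\ngA\t1\t2\ngA\t3\t4\n")
        with pytest.raises(DatasetError, match="gA"):
            read_expression(path)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(DatasetError):
            read_expression(path)

    def test_non_numeric_cell_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\ts1\ts2\ngA\t1\tX\ngB\t3\t4\n")
        with pytest.raises(DatasetError, match="non-numeric"):
            read_expression(path)


class TestFoldChanges:
    def test_identical_groups_give_zero(self):
        X = np.random.default_rng(1).standard_normal((5, 4))
        expr = _matrix(np.hstack([X[:, :2], X[:, :2]]),
                       samples=["t1", "t2", "c1", "c2"])
        fc, table = compute_fold_changes(
            expr, {"ct": {"treatment": ["t1", "t2"], "control": ["c1", "c2"]}})
        np.testing.assert_allclose(fc.to_array(), 0.0, atol=1e-12)
        assert fc.value_kind == "fold_change"

    def test_doubling_gives_log2fc_one(self):
        base = np.random.default_rng(2).standard_normal((4, 2))
        expr = _matrix(np.hstack([base + 1.0, base]),
                       samples=["t1", "t2", "c1", "c2"])
        fc, _ = compute_fold_changes(
            expr, {"ct": {"treatment": ["t1", "t2"], "control": ["c1", "c2"]}})
        np.testing.assert_allclose(fc.to_array(), 1.0, atol=1e-12)

    def test_swapping_groups_negates_log2fc(self, rng):
        expr = _matrix(rng.standard_normal((6, 6)))
        samples = expr.sample_ids
        fwd, _ = compute_fold_changes(
            expr, {"c": {"treatment": samples[:3], "control": samples[3:]}})
        rev, _ = compute_fold_changes(
            expr, {"c": {"treatment": samples[3:], "control": samples[:3]}})
        np.testing.assert_allclose(fwd.to_array(), -rev.to_array(), atol=1e-12)

    def test_singleton_group_flags_p_missing(self, rng):
        expr = _matrix(rng.standard_normal((4, 3)))
        fc, table = compute_fold_changes(
            expr, {"c": {"treatment": [expr.sample_ids[0]],
                         "control": expr.sample_ids[1:]}})
        assert np.isfinite(fc.to_array()).all()
        assert table["p"].isna().all()

    def test_q_bounds_and_order(self, rng):
        expr = _matrix(rng.standard_normal((30, 10)))
        samples = expr.sample_ids
        _, table = compute_fold_changes(
            expr, {"c": {"treatment": samples[:5], "control": samples[5:]}})
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert table["q"].between(0, 1).all()

    def test_requires_intensity(self):
        expr = _matrix(np.ones((3, 4)), kind="fold_change")
        with pytest.raises(DatasetError):
            compute_fold_changes(expr, {"c": {"treatment": ["s0"], "control": ["s1"]}})


class TestCombine:
    def test_single_matrix_identity(self, rng):
        expr = _matrix(rng.standard_normal((4, 3)))
        combined = combine_datasets([expr])
        np.testing.assert_allclose(combined.to_array(), expr.to_array())

    def test_sample_counts_add(self, rng):
        a = _matrix(rng.standard_normal((4, 3)), samples=["a1", "a2", "a3"])
        b = _matrix(rng.standard_normal((4, 2)), samples=["b1", "b2"])
        combined = combine_datasets([a, b])
        assert combined.n_samples == 5

    def test_gene_outside_intersection_dropped(self, rng):
        a = _matrix(rng.standard_normal((3, 2)), genes=["g0", "g1", "g2"],
                    samples=["a1", "a2"])
        b = _matrix(rng.standard_normal((2, 2)), genes=["g0", "g1"],
                    samples=["b1", "b2"])
        combined = combine_datasets([a, b])
        assert combined.gene_ids == ["g0", "g1"]

    def test_associative_up_to_column_order(self, rng):
        mats = [_matrix(rng.standard_normal((4, 2)),
                        samples=[f"d{i}s{j}" for j in range(2)])
                for i in range(3)]
        left = combine_datasets([combine_datasets(mats[:2]), mats[2]])
        right = combine_datasets([mats[0], combine_datasets(mats[1:])])
        pd.testing.assert_frame_equal(left.values, right.values)

    def test_mixed_kind_errors(self, rng):
        a = _matrix(rng.standard_normal((3, 2)), samples=["a1", "a2"])
        b = _matrix(rng.standard_normal((3, 2)), samples=["b1", "b2"],
                    kind="fold_change")
        with pytest.raises(DatasetError):
            combine_datasets([a, b])


class TestHomogeneity:
    def test_identical_samples_give_one(self, rng):
        col = rng.standard_normal(20)
        expr = _matrix(np.column_stack([col] * 4))
        assert dataset_homogeneity(expr) == pytest.approx(1.0)

    def test_orthogonal_samples_give_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])  # PCC(a, b) = 0
        expr = _matrix(np.column_stack([a, b]))
        assert dataset_homogeneity(expr) == pytest.approx(0.0, abs=1e-12)

    def test_three_samples_median_matches_enumeration(self, rng):
        X = rng.standard_normal((30, 3))
        expr = _matrix(X)
        pccs = [np.corrcoef(X[:, i], X[:, j])[0, 1]
                for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert dataset_homogeneity(expr) == pytest.approx(np.median(pccs))

    def test_invariant_to_reordering_and_per_sample_offsets(self, rng):
        X = rng.standard_normal((30, 5))
        expr = _matrix(X)
        shifted = _matrix(X + rng.standard_normal(5)[None, :],
                          samples=expr.sample_ids)
        assert dataset_homogeneity(shifted) == pytest.approx(
            dataset_homogeneity(expr), abs=1e-10)
        reordered = expr.subset(samples=list(reversed(expr.sample_ids)))
        assert dataset_homogeneity(reordered) == pytest.approx(
            dataset_homogeneity(expr), abs=1e-12)


class TestCategorySets:
    def _cats(self):
        return FunctionalCategorySet({
            "allexp": {f"g{i}": "experimental" for i in range(4)},
            "mixed": {**{f"g{i}": "experimental" for i in range(5)},
                      **{f"h{i}": "computational" for i in range(5)}},
            "smallcomp": {**{f"g{i}": "experimental" for i in range(3)},
                          "h9": "computational"},
        })

    def test_experimental_filter_keeps_all_experimental(self):
        out = filter_by_evidence(self._cats(), "experimental")
        assert out.members("allexp") == [f"g{i}" for i in range(4)]

    def test_mixed_category_restricted(self):
        out = filter_by_evidence(self._cats(), "experimental")
        assert len(out.members("mixed")) == 5

    def test_category_dropping_below_three(self):
        out = filter_by_evidence(self._cats(), "computational")
        assert "smallcomp" not in out
        assert len(out.members("mixed")) == 5

    def test_unknown_evidence_code_errors(self):
        with pytest.raises(DatasetError):
            FunctionalCategorySet({"c": {"g0": "guessed", "g1": "experimental",
                                         "g2": "experimental"}})

    def test_gmt_round_trip(self, tmp_path):
        cats = self._cats()
        path = tmp_path / "sets.gmt"
        write_gene_sets(cats, path)
        back = read_gene_sets(path)
        assert back.categories == cats.categories
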