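"""Normalization, half-binder reduction, and single-strong-probe enhancement."""

import numpy as np
import pytest

from fusionchip import (
    IntensityTable,
    NormalizationConfig,
    ScoringParams,
    Tag,
    ValidationError,
    enhance_single_strong_probe,
    normalize_scores,
    reduce_half_binders,
)

from conftest import make_heatmap


class TestNormalize:
    def test_equal_intensities_center_to_zero(self):
        t = IntensityTable("s", {f"p{i}": 100.0 for i in range(10)})
        assert all(v == 0.0 for v in normalize_scores(t).values())

    def test_256x_over_median_scores_about_eight(self):
        # log2(256) = 8; tiny pseudocount so the ratio is undistorted
        vals = {f"p{i}": 1000.0 for i in range(20)}
        vals["hot"] = 256_000.0
        s = normalize_scores(IntensityTable("s", vals), NormalizationConfig(pseudocount=1e-9))
        assert s["hot"] == pytest.approx(8.0, abs=1e-6)

    def test_method_none_is_identity(self):
        vals = {"a": 3.0, "b": 7.5}
        s = normalize_scores(IntensityTable("s", vals), NormalizationConfig(method="none"))
        assert s == vals

    def test_negatives_floored_at_zero(self):
        vals = {"lo": 1.0, "m1": 100.0, "m2": 100.0, "m3": 100.0}
        s = normalize_scores(IntensityTable("s", vals))
        assert s["lo"] == 0.0

    def test_empty_table_is_error(self):
        with pytest.raises(ValidationError):
            normalize_scores(IntensityTable("s", {}))

    def test_reference_probes_pin_the_baseline(self):
        # elevate most non-reference probes; centering on the reference set
        # must keep reference-level probes at score 0
        vals = {f"c{i}": 16_000.0 for i in range(30)}
        vals.update({f"g{i}": 1000.0 for i in range(10)})
        ref = {f"g{i}" for i in range(10)}
        s_ref = normalize_scores(IntensityTable("s", vals), reference_ids=ref)
        assert s_ref["g0"] == pytest.approx(0.0, abs=1e-9)
        assert s_ref["c0"] == pytest.approx(4.0, abs=0.01)
        # an all-probe median would sit at the elevated level instead
        s_all = normalize_scores(IntensityTable("s", vals))
        assert s_all["c0"] == 0.0

    def test_bad_config_rejected(self):
        with pytest.raises(ValidationError):
            NormalizationConfig(method="quantile")
        with pytest.raises(ValidationError):
            NormalizationConfig(pseudocount=0.0)


class TestReduceHalfBinders:
    def test_quarter_of_probes_at_70pct_zeroes_row(self):
        # 2/8 = 25% of probes >= 0.7 * 5.0 = 3.5 -> whole row zeroed
        m = np.zeros((4, 8))
        m[0] = [5.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        out = reduce_half_binders(make_heatmap(m))
        assert np.all(out.matrix[0] == 0.0)
        assert out.row_tags[0] is Tag.ZEROED
        assert np.array_equal(out.matrix[1:], m[1:])

    def test_three_probes_at_cutoff_zeroes_row(self):
        # count trigger: three probes >= 3.0 even though 3/40 < 25%
        m = np.zeros((3, 40))
        m[1] = [3.2, 3.1, 3.0] + [0.1] * 37
        out = reduce_half_binders(make_heatmap(m))
        assert np.all(out.matrix[1] == 0.0)
        assert out.row_tags[1] is Tag.ZEROED

    def test_all_zero_heatmap_unchanged_untagged(self):
        out = reduce_half_binders(make_heatmap(np.zeros((5, 6))))
        assert np.all(out.matrix == 0.0)
        assert all(t is Tag.NONE for t in out.row_tags + out.col_tags)

    def test_weak_halfbinding_tagged_values_kept(self):
        # neither zeroing trigger fires, but 3/8 >= 25% of probes >= 0.5*4.0
        row = [4.0, 2.5, 2.2, 0.1, 0.1, 0.1, 0.1, 0.1]
        m = np.zeros((4, 8))
        m[0] = row
        out = reduce_half_binders(make_heatmap(m))
        assert out.row_tags[0] is Tag.WEAK
        assert np.array_equal(out.matrix[0], row)

    def test_lone_strong_probe_does_not_self_trigger(self):
        # the true-positive signature: one outlier in a short row must
        # neither zero nor weak-tag its own row/column
        m = np.zeros((3, 4))
        m[1, 2] = 5.0
        out = reduce_half_binders(make_heatmap(m))
        assert out.matrix[1, 2] == 5.0
        assert out.row_tags[1] is Tag.NONE and out.col_tags[2] is Tag.NONE

    def test_column_rule_mirrors_row_rule(self):
        m = np.zeros((8, 4))
        m[:, 0] = [5.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        out = reduce_half_binders(make_heatmap(m))
        assert np.all(out.matrix[:, 0] == 0.0)
        assert out.col_tags[0] is Tag.ZEROED

    def test_never_increases_any_entry(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = rng.lognormal(0, 1, size=(6, 9))
            out = reduce_half_binders(make_heatmap(m))
            assert np.all(out.matrix <= m + 1e-12)

    def test_permutation_equivariance(self):
        # decisions are taken simultaneously on the input, so relabelling
        # rows/columns commutes with the filter
        rng = np.random.default_rng(13)
        for _ in range(10):
            m = rng.lognormal(0, 1, size=(7, 8))
            m[rng.integers(7), :] += 4.0
            pr, pc = rng.permutation(7), rng.permutation(8)
            direct = reduce_half_binders(make_heatmap(m))
            permuted = reduce_half_binders(make_heatmap(m[np.ix_(pr, pc)]))
            assert np.allclose(permuted.matrix, direct.matrix[np.ix_(pr, pc)])
            assert [direct.row_tags[i] for i in pr] == permuted.row_tags
            assert [direct.col_tags[j] for j in pc] == permuted.col_tags

    def test_reapplication_is_monotone(self):
        # the one-pass filter takes all its decisions on the input matrix;
        # a second application can only shrink the signal further — it never
        # resurrects a value and never removes a zeroed or weak tag
        rng = np.random.default_rng(42)
        order = {Tag.NONE: 0, Tag.WEAK: 1, Tag.ZEROED: 2}
        for _ in range(40):
            m = np.maximum(rng.normal(0, 0.3, size=(9, 11)), 0.0)
            if rng.random() < 0.7:
                m[rng.integers(9), :] += 4.0
            if rng.random() < 0.5:
                m[:, rng.integers(11)] += 4.0
            m[rng.integers(9), rng.integers(11)] += 5.0
            once = reduce_half_binders(make_heatmap(m))
            twice = reduce_half_binders(once)
            assert np.all(twice.matrix <= once.matrix)
            for t1, t2 in zip(once.row_tags + once.col_tags, twice.row_tags + twice.col_tags):
                assert order[t2] >= order[t1]

    def test_fixed_point_on_clean_single_probe_signal(self):
        # a lone strong probe over flat background is untouched, and the
        # filtered result is a true fixed point
        m = np.zeros((6, 8))
        m[2, 4] = 5.0
        once = reduce_half_binders(make_heatmap(m))
        twice = reduce_half_binders(once)
        assert np.array_equal(once.matrix, m)
        assert np.array_equal(twice.matrix, m)
        assert once.row_tags == twice.row_tags and once.col_tags == twice.col_tags


class TestEnhance:
    def test_gap_above_margin_promotes_to_six(self):
        m = np.full((5, 5), 0.2)
        m[2, 3] = 2.0
        m[0, 0] = 1.1
        out = enhance_single_strong_probe(reduce_half_binders(make_heatmap(m)))
        assert out.matrix[2, 3] == 6.0

    def test_weak_tagged_row_caps_promotion_at_three(self):
        m = np.zeros((5, 8))
        m[1] = [2.0, 1.1, 1.0, 0.1, 0.1, 0.1, 0.1, 0.1]  # weak-tagged row
        filtered = reduce_half_binders(make_heatmap(m))
        assert filtered.row_tags[1] is Tag.WEAK
        out = enhance_single_strong_probe(filtered)
        assert out.matrix[1, 0] == 3.0

    def test_gap_below_margin_leaves_heatmap_unchanged(self):
        m = np.full((4, 4), 0.2)
        m[0, 0], m[3, 3] = 2.0, 1.3  # gap 0.7 < 0.8
        out = enhance_single_strong_probe(make_heatmap(m))
        assert np.array_equal(out.matrix, m)

    def test_tied_maxima_are_not_enhanced(self):
        m = np.zeros((3, 3))
        m[0, 0] = m[2, 2] = 2.0
        out = enhance_single_strong_probe(make_heatmap(m))
        assert np.array_equal(out.matrix, m)

    def test_modifies_at_most_the_argmax_cell(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            m = np.maximum(rng.normal(0, 0.5, size=(6, 7)), 0)
            hm = make_heatmap(m)
            out = enhance_single_strong_probe(hm)
            diff = np.argwhere(out.matrix != m)
            assert len(diff) <= 1
            if len(diff) == 1:
                assert tuple(diff[0]) == np.unravel_index(np.argmax(m), m.shape)

    def test_single_cell_heatmap_unchanged(self):
        out = enhance_single_strong_probe(make_heatmap([[4.2]]))
        assert out.matrix[0, 0] == 4.2

    def test_boundary_gap_exactly_margin_promotes(self):
        m = np.zeros((2, 2))
        m[0, 0], m[1, 1] = 1.6, 0.8  # gap exactly 0.8
        out = enhance_single_strong_probe(make_heatmap(m))
        assert out.matrix[0, 0] == 6.0
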