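"""kd-tree sample ordering, TNoM, and the cooperative-repression test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedfold.expression import (
    Configuration,
    SamplePoint,
    choose_best_configuration,
    configurations,
    differential_repression_test,
    kd_sort,
    least_accessible_set,
    order_samples,
    random_subset_null,
    tnom,
    tnom_score,
)
from seedfold.synthetic import (
    MIRNA_ID,
    RBP_ID,
    SyntheticSpec,
    generate_expression,
)

from oracles import tnom_pvalue_enumeration, tnom_score_naive


def _pts(coords):
    return [SamplePoint(f"s{i}", float(x), float(y)) for i, (x, y) in enumerate(coords)]


class TestKdSort:
    def test_hand_traced_two_level_tree(self):
        ordered = kd_sort(_pts([(1, 1), (2, 4), (3, 2), (4, 3)]))
        assert [(p.x, p.y) for p in ordered] == [(1, 1), (2, 4), (3, 2), (4, 3)]

    def test_single_point(self):
        pts = _pts([(5, 5)])
        assert kd_sort(pts) == pts

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=1,
            max_size=40,
        )
    )
    def test_output_is_permutation(self, coords):
        pts = _pts(coords)
        ordered = kd_sort(pts)
        assert sorted(p.sample_id for p in ordered) == sorted(
            p.sample_id for p in pts
        )

    def test_joint_extremes_land_at_the_ends(self):
        rng = np.random.default_rng(2)
        coords = [(x, y) for x, y in rng.normal(0, 1, size=(30, 2))]
        coords += [(10, 10), (-10, -10)]
        ordered = kd_sort(_pts(coords))
        assert (ordered[-1].x, ordered[-1].y) == (10, 10)
        assert (ordered[0].x, ordered[0].y) == (-10, -10)


class TestConfigurations:
    def test_n4(self):
        cfgs = configurations(_pts([(i, i) for i in range(4)]))
        assert [c.k for c in cfgs] == [1, 2]
        assert cfgs[1].A == ("s2", "s3") and cfgs[1].B == ("s0", "s1")

    def test_n5_middle_sample_unused(self):
        cfgs = configurations(_pts([(i, i) for i in range(5)]))
        assert [c.k for c in cfgs] == [1, 2]
        used = set(cfgs[1].A) | set(cfgs[1].B)
        assert "s2" not in used

    def test_n60_gives_30_configurations(self):
        cfgs = configurations(_pts([(i, 0) for i in range(60)]))
        assert len(cfgs) == 30

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            Configuration(k=1, A=("s0",), B=("s0",))


class TestTNoM:
    def test_perfect_separation(self):
        res = tnom([1, 2], [3, 4])
        assert res.score == 0
        assert res.p_value == pytest.approx(1 / 6)

    def test_wrong_orientation_is_worst_case(self):
        assert tnom([3, 4], [1, 2]).score == 2

    def test_interleaved(self):
        assert tnom([1, 3], [2, 4]).score == 1

    def test_two_sided_takes_better_orientation(self):
        assert tnom([3, 4], [1, 2], one_sided=False).score == 0

    def test_ties_use_thresholds_between_distinct_values_only(self):
        # a threshold cannot split the tied 2s, so separation is imperfect
        assert tnom_score([1, 2], [2, 3]) == 1

    @pytest.mark.parametrize("seed", range(15))
    def test_pvalue_equals_enumeration(self, seed):
        """Exact agreement with label-permutation enumeration, |A|+|B| <= 10."""
        rng = np.random.default_rng(seed)
        nA = int(rng.integers(1, 6))
        nB = int(rng.integers(1, 11 - nA))
        vals = rng.permutation(np.arange(nA + nB, dtype=float))
        A, B = list(vals[:nA]), list(vals[nA:])
        one_sided = bool(seed % 2)
        res = tnom(A, B, one_sided=one_sided)
        assert res.score == tnom_score_naive(A, B, one_sided)
        assert res.p_value == pytest.approx(
            float(tnom_pvalue_enumeration(A, B, one_sided)), rel=1e-12
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            tnom([], [1.0])


def _toy_expression(n_targets=30, n_samples=12, seed=0, phi=None, shift=0.0):
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(n_samples)]
    genes = [f"G{i:03d}" for i in range(n_targets)]
    mat = rng.normal(0, 1, size=(n_targets, n_samples))
    df = pd.DataFrame(mat, index=genes, columns=samples)
    if phi and shift:
        df.loc[list(phi), samples[n_samples // 2 :]] -= shift
    return df, genes


class TestDifferentialRepression:
    def test_phi_with_smallest_p_captures_phi_exactly(self):
        df, genes = _toy_expression(seed=1)
        phi = genes[:6]
        # make phi genes perfectly repressed in A (= the last half samples)
        cfg = Configuration(
            k=6, A=tuple(df.columns[6:]), B=tuple(df.columns[:6])
        )
        df.loc[phi, list(cfg.A)] = -10.0
        df.loc[phi, list(cfg.B)] = 10.0
        res = differential_repression_test(df, genes, cfg, phi)
        assert res.b_star == len(phi)
        assert res.n_star == len(phi)

    def test_random_phi_is_null(self):
        """Random Φ gives well-calibrated enrichment p-values."""
        hits = 0
        for s in range(60):
            df, genes = _toy_expression(seed=200 + s)
            rng = np.random.default_rng(s)
            phi = list(rng.choice(genes, size=6, replace=False))
            cfg = Configuration(
                k=6, A=tuple(df.columns[6:]), B=tuple(df.columns[:6])
            )
            if differential_repression_test(df, genes, cfg, phi).p_value <= 0.05:
                hits += 1
        assert hits <= 9  # nominal 3, generous binomial slack

    def test_missing_targets_excluded_with_warning(self, caplog):
        df, genes = _toy_expression()
        cfg = Configuration(k=3, A=tuple(df.columns[9:]), B=tuple(df.columns[:3]))
        res = differential_repression_test(
            df, genes + ["MISSING"], cfg, genes[:3]
        )
        assert res.N == len(genes)


def _sample_pts(df):
    return [
        SamplePoint(c, float(i), float(i)) for i, c in enumerate(df.columns)
    ]


class TestChooseBestConfiguration:
    def test_returns_min_over_k(self):
        df, genes = _toy_expression(seed=3)
        pts = _sample_pts(df)
        _, best, trace = choose_best_configuration(df, genes, pts, genes[:5])
        assert best.p_value == pytest.approx(trace.p_value.min())

    def test_planted_effect_recovers_informative_k(self):
        """The planted joint-high block is 10 of 40 samples, so the selected
        configuration size should land within +/-2 of k=10 in >= 80% of 20
        seeded panels (and the enrichment should be strong throughout)."""
        from seedfold.expression import sample_points

        genes = [f"G{i:04d}" for i in range(100)]
        phi = genes[::5]  # spread over the id space so deterministic
        # tie-breaks by gene id cannot correlate with Φ membership
        near = 0
        for seed in range(1, 21):
            spec = SyntheticSpec(seed=seed)
            mrna, mirna = generate_expression(spec, phi, genes)
            pts = sample_points(mirna, mrna, MIRNA_ID, RBP_ID)
            ordered = order_samples(pts, "joint")
            cfg, res, _ = choose_best_configuration(mrna, genes, ordered, phi)
            assert res.p_value < 1e-3
            if abs(cfg.k - 10) <= 2:
                near += 1
        assert near >= 16


class TestRandomSubsetNull:
    def test_zero_draws_rejected(self):
        df, genes = _toy_expression()
        with pytest.raises(ValueError):
            random_subset_null(df, genes, _sample_pts(df), genes[:5], n_draws=0)

    def test_insufficient_pool_rejected(self):
        df, genes = _toy_expression(n_targets=8)
        with pytest.raises(ValueError):
            random_subset_null(df, genes, _sample_pts(df), genes[:6], n_draws=5)

    def test_null_phi_not_extreme(self):
        """Without a planted effect Φ is exchangeable with random subsets, so
        its empirical p should not be extreme in (at least) most replicates."""
        ps = []
        for s in range(3):
            df, genes = _toy_expression(seed=9 + s)
            pts = _sample_pts(df)
            ps.append(
                random_subset_null(df, genes, pts, genes[:6], n_draws=50, seed=4 + s)
            )
        assert max(ps) > 0.05


class TestLeastAccessibleSet:
    def test_top_20_percent(self, default_ranked):
        ranked, _ = default_ranked
        phi = least_accessible_set(ranked)
        assert len(phi.genes) == int(np.floor(0.2 * len(ranked)))
        assert phi.genes[0] == ranked.windows[0].gene_id
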