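"""Synthetic data generators: distributional oracles, nesting, partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wtofid import (
    EnsembleDesign,
    generate_modular_expression,
    generate_random_expression,
    nested_subsample,
    partition_genes,
)
from wtofid.simulate import child_seed, derived_rng


class TestUniformNull:
    def test_entries_in_unit_interval(self):
        m = generate_random_expression(1000, 10, seed=1)
        assert m.values.shape == (1000, 10)
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_grand_mean_near_half(self):
        # law of large numbers: 338,000 U(0,1) draws, mean 0.5 ± 0.01
        m = generate_random_expression(1000, 338, seed=5)
        assert abs(m.values.mean() - 0.5) < 0.01

    def test_seeded_determinism(self):
        a = generate_random_expression(2, 3, seed=7)
        b = generate_random_expression(2, 3, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        c = generate_random_expression(2, 3, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            generate_random_expression(1, 10, seed=0)
        with pytest.raises(ValueError, match="n_samples"):
            generate_random_expression(10, 0, seed=0)


class TestModularFactorModel:
    def test_within_block_correlation_recovers_rho(self):
        # factor model: corr(sqrt(rho)f + sqrt(1-rho)e_i, ...) = rho exactly,
        # so the empirical mean over a 50-gene block at n=5000 sits at 0.6
        m = generate_modular_expression(200, 5000, [50], 0.6, seed=11)
        C = np.corrcoef(m.values[:50])
        mean_within = C[np.triu_indices(50, k=1)].mean()
        assert abs(mean_within - 0.6) < 0.03
        # genes outside the block stay uncorrelated with it
        cross = np.corrcoef(m.values)[ :50, 50:]
        assert abs(cross.mean()) < 0.01

    def test_rho_zero_gives_independent_data(self):
        m = generate_modular_expression(100, 2000, [40], 0.0, seed=3)
        C = np.corrcoef(m.values[:40])
        off = C[np.triu_indices(40, k=1)]
        assert abs(off.mean()) < 0.01
        assert np.abs(off).max() < 0.12  # ~4.8 sd at n=2000

    def test_seeded_determinism(self):
        a = generate_modular_expression(30, 10, [5, 5], 0.5, seed=2)
        b = generate_modular_expression(30, 10, [5, 5], 0.5, seed=2)
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(ValueError, match="within_block_correlation"):
            generate_modular_expression(10, 5, [5], rho, seed=0)

    def test_oversized_blocks_rejected(self):
        with pytest.raises(ValueError, match="block sizes"):
            generate_modular_expression(10, 5, [8, 8], 0.5, seed=0)


class TestNestedSubsample:
    def test_levels_are_strictly_nested(self):
        full = generate_random_expression(5, 338, seed=0)
        nested = nested_subsample(full, [10, 20, 50], seed=1)
        s10 = set(nested.levels[10].sample_ids)
        s20 = set(nested.levels[20].sample_ids)
        s50 = set(nested.levels[50].sample_ids)
        assert s10 < s20 < s50 < set(full.sample_ids)
        for level in nested.levels.values():
            assert level.gene_ids == full.gene_ids

    def test_full_size_level_is_column_permutation(self):
        full = generate_random_expression(4, 6, seed=0)
        nested = nested_subsample(full, [6], seed=9)
        level = nested.levels[6]
        assert sorted(level.sample_ids) == sorted(full.sample_ids)
        order = [full.sample_ids.index(s) for s in level.sample_ids]
        np.testing.assert_array_equal(level.values, full.values[:, order])

    def test_seeded_determinism(self):
        full = generate_random_expression(4, 100, seed=0)
        a = nested_subsample(full, [5, 10], seed=3)
        b = nested_subsample(full, [5, 10], seed=3)
        assert a.levels[10].sample_ids == b.levels[10].sample_ids

    def test_oversized_request_rejected(self):
        full = generate_random_expression(4, 10, seed=0)
        with pytest.raises(ValueError, match="available"):
            nested_subsample(full, [5, 20], seed=0)

    def test_non_increasing_sizes_rejected(self):
        full = generate_random_expression(4, 10, seed=0)
        with pytest.raises(ValueError, match="increasing"):
            nested_subsample(full, [10, 5], seed=0)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None)
    def test_nesting_holds_for_any_seed(self, seed):
        full = generate_random_expression(3, 30, seed=0)
        nested = nested_subsample(full, [4, 9, 17], seed=seed)
        ids = [set(nested.levels[k].sample_ids) for k in (4, 9, 17)]
        assert ids[0] < ids[1] < ids[2]


class TestPartitionGenes:
    def test_exact_fit_covers_every_gene_once(self):
        m = generate_random_expression(2000, 3, seed=0)
        groups = partition_genes(m, EnsembleDesign(n_groups=2, group_size=1000, seed=1))
        seen = [g for grp in groups for g in grp.gene_ids]
        assert len(seen) == 2000 and len(set(seen)) == 2000

    def test_groups_disjoint_and_leftovers_dropped(self):
        m = generate_random_expression(107, 3, seed=0)
        groups = partition_genes(m, EnsembleDesign(n_groups=5, group_size=20, seed=4))
        assert [g.n_genes for g in groups] == [20] * 5
        union = set().union(*(set(g.gene_ids) for g in groups))
        assert len(union) == 100  # 7 genes omitted

    def test_too_few_genes_rejected(self):
        m = generate_random_expression(10, 3, seed=0)
        with pytest.raises(ValueError, match="partition needs"):
            partition_genes(m, EnsembleDesign(n_groups=3, group_size=4, seed=0))

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=15, deadline=None)
    def test_disjointness_for_any_seed(self, seed):
        m = generate_random_expression(50, 3, seed=0)
        groups = partition_genes(m, EnsembleDesign(n_groups=4, group_size=11, seed=seed))
        all_ids = [g for grp in groups for g in grp.gene_ids]
        assert len(all_ids) == len(set(all_ids)) == 44


class TestSeedScheme:
    def test_derived_streams_are_purpose_separated(self):
        a = derived_rng(1, "alpha").random(5)
        b = derived_rng(1, "beta").random(5)
        a2 = derived_rng(1, "alpha").random(5)
        np.testing.assert_array_equal(a, a2)
        assert not np.array_equal(a, b)

    def test_child_seed_stable_and_bounded(self):
        s = child_seed(42, 3, "subsample")
        assert s == child_seed(42, 3, "subsample")
        assert 0 <= s < 2**31
        assert s != child_seed(42, 4, "subsample")
        assert s != child_seed(42, 3, "null-data")
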