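import numpy as np
import pytest
from scipy import stats

from wunifrac.errors import ContractError, EnumerationCapError, InvalidCountError
from wunifrac.io import parse_newick
from wunifrac.significance import (
    exact_pvalue,
    mc_pvalue,
    pairwise_significance,
    shuffle_labels,
)
from wunifrac.transform import expand
from wunifrac.tree import EnvironmentTable, validate

from conftest import random_lt


class TestShuffleLabels:
    def test_compact_shuffle_moves_whole_bundles(self, figs):
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(20):
            out = shuffle_labels(figs["fig2"], "compact", rng)
            seen.add(tuple(sorted((l, s, c) for l in out.env
                           for s, c in out.env.bundle(l).items())))
        assert seen == {
            (("A", "Sample1", 4), ("B", "Sample2", 4)),
            (("A", "Sample2", 4), ("B", "Sample1", 4)),
        }

    def test_expanded_shuffle_requires_expanded_form(self, figs):
        rng = np.random.default_rng(0)
        with pytest.raises(ContractError):
            shuffle_labels(figs["fig2"], "expanded", rng)
        out = shuffle_labels(figs["fig3"], "expanded", rng)
        assert len(out.root.leaves()) == 8

    @pytest.mark.parametrize("seed", range(10))
    def test_totals_and_topology_conserved(self, seed):
        lt = random_lt(seed)
        rng = np.random.default_rng(seed)
        out = shuffle_labels(lt, "compact", rng)
        assert out.root == lt.root
        for s in lt.samples:
            assert out.env.total(s) == lt.env.total(s)


class TestExactPvalue:
    def test_expanded_semantics_count_separated_labelings(self, figs):
        res = exact_pvalue(figs["fig3"], "Sample1", "Sample2", mode="expanded")
        assert res.n_null == 70 and res.n_ge == 2
        assert res.p_value == 2 / 70

    def test_compact_semantics_on_bundled_counts_is_certain(self, figs):
        res = exact_pvalue(figs["fig2"], "Sample1", "Sample2", mode="compact")
        assert res.n_null == 2 and res.p_value == 1.0

    def test_unit_count_tree_is_certain_in_both_modes(self, figs):
        for mode in ("compact", "expanded"):
            assert exact_pvalue(
                figs["fig1"], "Sample1", "Sample2", mode=mode
            ).p_value == 1.0

    def test_scaled_counts_and_lengths_change_nothing_in_compact_mode(self, figs):
        res = exact_pvalue(
            figs["fig2_scaled"], "Sample1", "Sample2", mode="compact"
        )
        assert res.p_value == 1.0

    def test_expanded_mode_discrepancy_against_compact(self, figs):
        compact = exact_pvalue(figs["fig2"], "Sample1", "Sample2", "compact")
        expanded = exact_pvalue(figs["fig2"], "Sample1", "Sample2", "expanded")
        assert compact.p_value == 1.0
        assert expanded.p_value == 2 / 70

    @pytest.mark.parametrize("seed", [2, 5, 9])
    def test_expanded_p_is_invariant_to_pre_expansion(self, seed):
        lt = random_lt(seed, n_leaves=4, max_count=2)
        a, b = lt.samples[:2]
        direct = exact_pvalue(lt, a, b, mode="expanded")
        pre = exact_pvalue(expand(lt), a, b, mode="expanded")
        assert direct.p_value == pre.p_value
        assert direct.n_null == pre.n_null

    def test_near_zero_branch_lengths_barely_move_the_p_value(self, figs):
        """Un-clustered variant: unit leaves on small positive branches."""
        tree = parse_newick(
            "((A1:0.01,A2:0.01,A3:0.01,A4:0.01)A:0.1,"
            "(B1:0.01,B2:0.01,B3:0.01,B4:0.01)B:0.1);"
        )
        env = EnvironmentTable(
            {f"A{k}": {"Sample1": 1} for k in range(1, 5)}
            | {f"B{k}": {"Sample2": 1} for k in range(1, 5)}
        )
        lt = validate(tree, env)
        res = exact_pvalue(lt, "Sample1", "Sample2", mode="expanded")
        assert abs(res.p_value - 2 / 70) < 0.01

    def test_enumeration_cap_raises_helpful_error(self, figs):
        with pytest.raises(EnumerationCapError):
            exact_pvalue(
                figs["fig2_scaled"], "Sample1", "Sample2", mode="expanded"
            )


class TestMonteCarlo:
    def test_reproducible_given_seed(self, figs):
        kw = dict(mode="expanded", n_perm=200, seed=42)
        r1 = mc_pvalue(figs["fig3"], "Sample1", "Sample2", **kw)
        r2 = mc_pvalue(figs["fig3"], "Sample1", "Sample2", **kw)
        assert r1.p_value == r2.p_value
        assert r1.seed == 42 and r1.n_null == 200

    def test_compact_two_bundle_tree_is_certain_for_any_seed(self, figs):
        for seed in (0, 1, 99, 2**30):
            res = mc_pvalue(
                figs["fig2"], "Sample1", "Sample2", "compact",
                n_perm=50, seed=seed,
            )
            assert res.p_value == 1.0

    def test_plus_one_correction(self, figs):
        res = mc_pvalue(
            figs["fig3"], "Sample1", "Sample2", "expanded",
            n_perm=100, seed=7, plus_one=True,
        )
        assert res.p_value == (res.n_ge + 1) / (res.n_null + 1)

    def test_zero_permutations_rejected(self, figs):
        with pytest.raises(InvalidCountError):
            mc_pvalue(figs["fig2"], "Sample1", "Sample2", n_perm=0)

    @pytest.mark.parametrize("seed", [3, 8])
    def test_converges_to_exact_enumeration(self, seed):
        """MC estimate at n_perm=1e5 falls inside the 99.9% binomial band
        around the exact p-value."""
        lt = random_lt(seed, n_leaves=6, max_count=2)
        a, b = lt.samples[:2]
        exact = exact_pvalue(lt, a, b, mode="expanded")
        mc = mc_pvalue(lt, a, b, mode="expanded", n_perm=10**5, seed=seed)
        lo, hi = stats.binom.interval(0.999, mc.n_null, exact.p_value)
        assert lo <= mc.n_ge <= hi


class TestPairwise:
    def test_two_sample_input_matches_single_pair_test(self, figs):
        res = pairwise_significance(figs["fig2"], method="exact")
        assert set(res) == {("Sample1", "Sample2")}
        single = exact_pvalue(figs["fig2"], "Sample1", "Sample2")
        assert res[("Sample1", "Sample2")].p_value == single.p_value

    def test_six_sample_fixture_yields_fifteen_probabilities(self):
        lt = random_lt(11, n_leaves=10, n_samples=6)
        res = pairwise_significance(lt, method="monte_carlo", n_perm=30, seed=1)
        assert len(res) == 15
        assert all(0.0 <= r.p_value <= 1.0 for r in res.values())

    def test_sample_mirroring_another_is_never_significant(self, figs):
        """A third sample placed identically to Sample1 ties every null
        labeling, so its pair with Sample1 has p = 1 under exact expanded
        enumeration."""
        lt = validate(
            figs["fig2"].root.copy(),
            EnvironmentTable(
                {"A": {"Sample1": 4, "C": 4}, "B": {"Sample2": 4}}
            ),
        )
        res = pairwise_significance(lt, mode="expanded", method="exact")
        assert res[("C", "Sample1")].p_value == 1.0

    def test_bonferroni_scales_and_clips(self):
        lt = random_lt(4, n_leaves=6, n_samples=3)
        plain = pairwise_significance(lt, method="monte_carlo", n_perm=40, seed=5)
        corr = pairwise_significance(
            lt, method="monte_carlo", n_perm=40, seed=5, bonferroni=True
        )
        for pair in plain:
            assert corr[pair].p_value == min(1.0, plain[pair].p_value * 3)
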