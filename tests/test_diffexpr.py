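import numpy as np
import pandas as pd
import pytest

from cernet import diffexpr
from cernet.diffexpr import (
    DEFAULT_LABELS,
    call_de,
    de_analysis,
    de_test,
    fold_change,
    standard_contrasts,
    venn_partition,
)
from cernet.errors import UserError
from cernet.simulate import SimulationConfig, generate_dataset

from conftest import small_matrix


def paired_matrix(a_vals, b_vals):
    """Two groups A (CM) and B (iPSC) sharing lines, one feature per column pair."""
    a_vals, b_vals = np.atleast_2d(a_vals), np.atleast_2d(b_vals)
    n = a_vals.shape[1]
    cols = {f"A{i}": a_vals[:, i] for i in range(n)}
    cols.update({f"B{i}": b_vals[:, i] for i in range(n)})
    groups = pd.DataFrame(
        {
            "genotype": ["WT"] * 2 * n,
            "state": ["CM"] * n + ["iPSC"] * n,
            "line_id": [f"W{i}" for i in range(n)] * 2,
        },
        index=list(cols),
    )
    return small_matrix(cols, groups), [f"A{i}" for i in range(n)], [f"B{i}" for i in range(n)]


class TestFoldChange:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([[2.0, 2.0]], [[1.0, 1.0]], 2.0),   # doubled means
            ([[3.0, 5.0]], [[3.0, 5.0]], 1.0),   # identical groups
            ([[4.0, 6.0]], [[1.0, 3.0]], 2.5),   # 5/2
        ],
    )
    def test_linear_mean_ratio(self, a, b, expected):
        m, ga, gb = paired_matrix(a, b)
        assert fold_change(m, ga, gb).iloc[0] == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        m, ga, gb = paired_matrix([[1.0, 1.0]], [[0.0, 0.0]])
        with pytest.raises(UserError):
            fold_change(m, ga, gb)

    def test_log2_matrix_antilogged(self):
        m, ga, gb = paired_matrix([[8.0, 8.0]], [[4.0, 4.0]])
        log2m = m.to_log2()
        assert fold_change(log2m, ga, gb).iloc[0] == pytest.approx(2.0)


class TestDETest:
    def test_identical_groups_paired_p_one(self):
        m, ga, gb = paired_matrix([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        assert de_test(m.to_log2(), ga, gb, paired=True).iloc[0] == 1.0

    def test_paired_t_oracle(self):
        # log2 pairs [1,2,3] vs [2,3,5]: t = -4, df = 2, p ~ 0.0572
        m, ga, gb = paired_matrix([[1.0, 2.0, 3.0]], [[2.0, 3.0, 5.0]])
        m = small_matrix(
            dict(zip(m.sample_ids, m.values.T.to_numpy())), m.sample_groups, scale="log2"
        )
        assert de_test(m, ga, gb, paired=True).iloc[0] == pytest.approx(0.0571909584, rel=1e-8)

    def test_two_tailed_symmetry(self):
        rng = np.random.default_rng(6)
        m, ga, gb = paired_matrix(rng.normal(8, 1, (5, 4)), rng.normal(8, 1, (5, 4)))
        p_ab = de_test(m, ga, gb, paired=True)
        p_ba = de_test(m, gb, ga, paired=True)
        np.testing.assert_allclose(p_ab, p_ba)
        np.testing.assert_allclose(
            de_test(m, ga, gb, paired=False), de_test(m, gb, ga, paired=False)
        )

    def test_group_size_guard(self):
        m, ga, gb = paired_matrix([[1.0]], [[2.0]])
        with pytest.raises(UserError):
            de_test(m, ga, gb, paired=True)


class TestCallDE:
    def _result(self, fc, p, **kw):
        idx = pd.Index([f"f{i}" for i in range(len(fc))])
        return call_de(pd.Series(fc, index=idx), pd.Series(p, index=idx), **kw)

    @pytest.mark.parametrize(
        "fc, p, expected",
        [
            (2.0, 0.049, "up"),      # boundary included by FC >= 2
            (1.99, 0.001, "none"),   # just below the cut
            (0.5, 0.01, "down"),     # boundary included by FC <= 0.5
            (4.0, 0.05, "none"),     # P threshold is strict
            (0.2, 0.06, "none"),
        ],
    )
    def test_printed_criteria_boundaries(self, fc, p, expected):
        assert self._result([fc], [p]).table["direction"].iloc[0] == expected

    def test_direction_consistent_with_fc(self):
        res = self._result([4.0, 0.25, 1.0], [0.01, 0.01, 0.01])
        assert res.up == {"f0"} and res.down == {"f1"}

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(UserError):
            call_de(
                pd.Series([2.0], index=["a"]), pd.Series([0.01], index=["b"])
            )


class TestVennPartition:
    def _de(self, called, universe):
        table = pd.DataFrame(
            {
                "fc": 1.0,
                "p_value": 1.0,
                "direction": ["up" if f in called else "none" for f in universe],
            },
            index=pd.Index(universe, name="feature_id"),
        )
        return diffexpr.DEResult("c", table)

    def test_seven_region_enumeration(self):
        universe = [f"g{i}" for i in range(1, 7)]
        a = self._de({"g1", "g2", "g3"}, universe)
        b = self._de({"g1", "g2", "g4"}, universe)
        c = self._de({"g2", "g4", "g5"}, universe)
        regions = venn_partition(a, b, c).regions
        assert regions[(True, True, False)] == {"g1"}
        assert regions[(True, True, True)] == {"g2"}
        assert regions[(True, False, False)] == {"g3"}
        assert regions[(False, True, True)] == {"g4"}
        assert regions[(False, False, True)] == {"g5"}
        assert regions[(True, False, True)] == set()

    def test_identical_sets_single_region(self):
        universe = ["g1", "g2", "g3"]
        d = self._de({"g1", "g2"}, universe)
        vp = venn_partition(d, d, d)
        nonempty = {k for k, v in vp.regions.items() if v}
        assert nonempty == {(True, True, True)}

    def test_sizes_sum_to_union(self):
        universe = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        des = [self._de(set(rng.choice(universe, 8, replace=False)), universe)
               for _ in range(3)]
        vp = venn_partition(*des)
        assert sum(vp.sizes().values()) == len(vp.union())
        assert vp.union() == des[0].called | des[1].called | des[2].called

    def test_custom_label_map(self):
        universe = ["g1"]
        d = self._de({"g1"}, universe)
        labels = {bits: f"R{i}" for i, bits in enumerate(DEFAULT_LABELS)}
        vp = venn_partition(d, d, d, labels=labels)
        assert set(vp.named_regions()) == set(labels.values())


class TestOnSyntheticData:
    def test_noise_free_calls_equal_planted_sets(self, noisefree_bundle):
        m = noisefree_bundle.combined()
        for label, contrast in standard_contrasts(m).items():
            de = de_analysis(m, contrast)
            truth = {
                f
                for f, eff in noisefree_bundle.truth.de_features[label].items()
                if abs(eff) >= 1.0
            }
            assert de.called == truth, label

    def test_noisy_sensitivity_and_null_false_calls(self):
        """sigma=0.3, 3 lines, planted |log2FC|=2: sensitivity >= 0.8."""
        from scipy.stats import binom

        cfg = SimulationConfig(seed=17, noise_sd=0.3, diff_effect_sd=0.0,
                               n_planted_circuits=0)
        b = generate_dataset(cfg)
        m = b.combined()
        label = "WT_CM_vs_WT_iPSC"
        de = de_analysis(m, standard_contrasts(m)[label])
        truth = set(b.truth.de_features[label])
        sens = len(de.called & truth) / len(truth)
        assert sens >= 0.8
        nulls = set(m.feature_ids) - truth - set(b.truth.escape_features)
        false_calls = len(de.called & nulls)
        assert false_calls <= binom.ppf(0.95, len(nulls), 0.05)
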