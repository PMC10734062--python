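import numpy as np
import pandas as pd
import pytest

from cernet.coexpression import (
    build_coexpression_network,
    correlate_pairs,
    edges_to_frame,
    pcc,
    pcc_pvalue,
)
from cernet.errors import UserError
from cernet.io import ExpressionMatrix

from conftest import small_matrix


class TestPCC:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [6, 4, 2], -1.0),
            ([1, 2, 3], [1, 3, 2], 0.5),
        ],
    )
    def test_hand_oracles(self, x, y, expected):
        assert pcc(x, y) == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(UserError):
            pcc([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(UserError):
            pcc([1, 2], [3, 4])


class TestPCCPValue:
    def test_r_zero_gives_one(self):
        assert pcc_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_t_cdf_oracle(self):
        # t = 0.2*2/sqrt(0.96) = 0.40825 on 4 df -> p = 0.704
        assert pcc_pvalue(0.2, 6) == pytest.approx(0.704, rel=1e-6)

    def test_monotone_in_n(self):
        ps = [pcc_pvalue(0.4, n) for n in (4, 8, 16, 32, 64)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_perfect_correlation_warns_minimal_p(self):
        with pytest.warns(UserWarning):
            p = pcc_pvalue(1.0, 5)
        assert 0 < p < 1e-300


def _matrix_with_features(rows, n_samples=8, seed=0):
    """rows: dict feature -> values (len n_samples); others filled randomly."""
    rng = np.random.default_rng(seed)
    data = {f: np.asarray(v, dtype=float) for f, v in rows.items()}
    df = pd.DataFrame(data, index=[f"S{i}" for i in range(n_samples)]).T
    groups = pd.DataFrame(
        {
            "genotype": ["WT"] * n_samples,
            "state": ["iPSC"] * (n_samples // 2) + ["CM"] * (n_samples - n_samples // 2),
            "line_id": [f"W{i}" for i in range(n_samples)],
        },
        index=df.columns,
    )
    return ExpressionMatrix(df, groups, scale="log2")


class TestBuildNetwork:
    def test_vectorized_equals_per_pair_loop(self, default_bundle):
        m = default_bundle.combined().to_log2()
        sponges = m.feature_ids[1200:1215]  # lncRNAs
        mrnas = m.feature_ids[:20]
        samples = m.sample_ids
        table = correlate_pairs(m, sponges, mrnas, samples)
        for row in table.sample(30, random_state=0).itertuples(index=False):
            x = m.values.loc[row.sponge, samples]
            y = m.values.loc[row.mrna, samples]
            assert row.pcc == pytest.approx(pcc(x, y), abs=1e-12)
            assert row.p_value == pytest.approx(pcc_pvalue(pcc(x, y), len(samples)), abs=1e-8)

    def test_thresholds_signed_and_strict(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 8)
        m = _matrix_with_features(
            {"s1": base, "g_anti": -base, "g_same": base + rng.normal(0, 0.01, 8)}
        )
        edges, _ = build_coexpression_network(
            m, ["s1"], ["g_anti", "g_same"], m.sample_ids
        )
        kept = {e.mrna_feature_id for e in edges}
        assert "g_same" in kept          # strong positive retained
        assert "g_anti" not in kept      # anti-correlated excluded (signed rule)
        # unsigned mode recovers the anti-correlated pair
        edges_abs, _ = build_coexpression_network(
            m, ["s1"], ["g_anti", "g_same"], m.sample_ids, signed=False
        )
        assert {e.mrna_feature_id for e in edges_abs} == {"g_anti", "g_same"}

    def test_r_below_cut_excluded_regardless_of_p(self):
        # r = 0.15 < 0.2 must be excluded even with a tiny p (many samples)
        rng = np.random.default_rng(12)
        n = 400
        x = rng.normal(0, 1, n)
        y = 0.15 * x + rng.normal(0, 1, n) * np.sqrt(1 - 0.15**2)
        groups = pd.DataFrame(
            {"genotype": ["WT"] * n, "state": ["iPSC"] * n,
             "line_id": [f"W{i}" for i in range(n)]},
            index=[f"S{i}" for i in range(n)],
        )
        df = pd.DataFrame({f"S{i}": [x[i], y[i], rng.normal()] for i in range(n)},
                          index=["s1", "g1", "pad"])
        m = ExpressionMatrix(df, groups, scale="log2")
        r = pcc(x, y)
        assert abs(r) < 0.2 and pcc_pvalue(r, n) < 0.05  # premise of the check
        edges, _ = build_coexpression_network(m, ["s1"], ["g1"], m.sample_ids)
        assert edges == []

    def test_noise_free_planted_pair_retained_with_r_one(self, noisefree_bundle):
        m = noisefree_bundle.combined()
        c = noisefree_bundle.truth.circuits[0]
        edges, _ = build_coexpression_network(
            m, [c["sponge_id"]], [c["mrna_id"]], m.sample_ids
        )
        assert len(edges) == 1
        assert edges[0].pcc == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_feature_and_sample_ordering(self, default_bundle):
        m = default_bundle.combined().to_log2()
        sponges = m.feature_ids[1200:1210]
        mrnas = m.feature_ids[:10]
        edges_fwd, _ = build_coexpression_network(m, sponges, mrnas, m.sample_ids)
        shuffled = ExpressionMatrix(
            m.values.iloc[::-1, ::-1], m.sample_groups, scale="log2"
        )
        edges_rev, _ = build_coexpression_network(
            shuffled, sponges[::-1], mrnas[::-1], m.sample_ids[::-1]
        )
        key = lambda es: {
            (e.sponge_feature_id, e.mrna_feature_id): (round(e.pcc, 12), round(e.p_value, 12))
            for e in es
        }
        assert key(edges_fwd) == key(edges_rev)

    def test_empty_de_lists_warn_and_return_empty(self, default_bundle):
        m = default_bundle.combined()
        with pytest.warns(UserWarning):
            edges, graph = build_coexpression_network(m, [], ["x"], m.sample_ids)
        assert edges == [] and graph.number_of_nodes() == 0

    def test_edges_frame_sorted(self, default_bundle):
        m = default_bundle.combined().to_log2()
        edges, _ = build_coexpression_network(
            m, m.feature_ids[1200:1240], m.feature_ids[:40], m.sample_ids
        )
        df = edges_to_frame(edges)
        assert list(df.columns)[:2] == ["sponge_feature_id", "mrna_feature_id"]
        assert df.equals(df.sort_values(["sponge_feature_id", "mrna_feature_id"],
                                        ignore_index=True))
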