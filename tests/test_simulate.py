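import numpy as np
import pytest

from cernet import coexpression
from cernet.errors import UserError
from cernet.pipeline import recover_circuits
from cernet.simulate import SimulationConfig, TruthManifest, generate_dataset, score_recovery


class TestDeterminism:
    def test_same_seed_same_bundle(self, tmp_path):
        cfg = dict(seed=3, n_mrna=120, n_lncrna=60, n_circrna=40, n_mirnas=80,
                   n_planted_circuits=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(SimulationConfig(**cfg)).write(d1)
        generate_dataset(SimulationConfig(**cfg)).write(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name

    def test_different_seed_differs(self):
        a = generate_dataset(SimulationConfig(seed=1, n_mrna=120, n_lncrna=60,
                                              n_circrna=40, n_mirnas=80,
                                              n_planted_circuits=4))
        b = generate_dataset(SimulationConfig(seed=2, n_mrna=120, n_lncrna=60,
                                              n_circrna=40, n_mirnas=80,
                                              n_planted_circuits=4))
        assert not np.allclose(a.combined().values, b.combined().values)


class TestPlantedStructure:
    def test_noise_free_escape_dosage_ratio_exact(self, noisefree_bundle):
        m = noisefree_bundle.combined()
        wt, ts = m.samples("WT"), m.samples("TS")
        esc = noisefree_bundle.truth.escape_features
        ratio = m.values.loc[esc, ts].mean(axis=1) / m.values.loc[esc, wt].mean(axis=1)
        np.testing.assert_allclose(ratio, 0.5, rtol=0, atol=1e-12)

    def test_small_noise_escape_ratio_converges(self):
        b = generate_dataset(SimulationConfig(seed=5, noise_sd=0.05, line_sd=0.0,
                                              n_lines_per_genotype=10))
        m = b.combined()
        wt, ts = m.samples("WT"), m.samples("TS")
        esc = b.truth.escape_features
        ratio = m.values.loc[esc, ts].mean(axis=1) / m.values.loc[esc, wt].mean(axis=1)
        np.testing.assert_allclose(ratio, 0.5, rtol=0.1)

    def test_noise_free_planted_pair_pcc_is_one(self, noisefree_bundle):
        m = noisefree_bundle.combined().to_log2()
        for c in noisefree_bundle.truth.circuits:
            r = coexpression.pcc(
                m.values.loc[c["sponge_id"]], m.values.loc[c["mrna_id"]]
            )
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_planted_ids_exist_and_targets_contain_true_pairs(self, default_bundle):
        ids = set(default_bundle.combined().feature_ids)
        pairs = set(zip(default_bundle.targets["mirna_id"],
                        default_bundle.targets["target_id"]))
        for c in default_bundle.truth.circuits:
            assert c["sponge_id"] in ids and c["mrna_id"] in ids
            for mirna in c["mirna_ids"]:
                assert (mirna, c["sponge_id"]) in pairs
                assert (mirna, c["mrna_id"]) in pairs

    def test_decoy_ratio_respected(self, default_bundle):
        truth_pairs = sum(len(c["mirna_ids"]) * 2
                          for c in default_bundle.truth.circuits)
        assert len(default_bundle.targets) == truth_pairs * 6  # 1 true + 5 decoys

    def test_null_world_yields_no_de_calls(self):
        """sigma=0, no planted effects: DE must return zero calls."""
        from cernet import diffexpr

        cfg = SimulationConfig(seed=9, noise_sd=0.0, line_sd=0.0,
                               frac_cm_regulated=0.0, n_planted_circuits=0,
                               ts_dosage_factor=1.0, frac_chrx=0.0,
                               n_mrna=200, n_lncrna=80, n_circrna=40)
        m = generate_dataset(cfg).combined()
        for contrast in diffexpr.standard_contrasts(m).values():
            de = diffexpr.de_analysis(m, contrast)
            assert de.called == set()

    def test_config_errors(self):
        with pytest.raises(UserError):
            SimulationConfig(n_planted_circuits=50, n_mrna=10, n_lncrna=30, n_circrna=30)
        with pytest.raises(UserError):
            SimulationConfig(ts_dosage_factor=0.0)
        with pytest.raises(UserError):
            SimulationConfig(circuit_beta=3.0)


class TestScoreRecovery:
    def _truth(self, pairs):
        return TruthManifest(
            de_features={},
            circuits=[{"sponge_id": s, "mirna_ids": ["m"], "mrna_id": g, "beta": 0.9}
                      for s, g in pairs],
            escape_features=[],
        )

    def test_perfect_and_empty(self):
        truth = self._truth([("s1", "g1"), ("s2", "g2")])
        assert score_recovery([("s1", "g1"), ("s2", "g2")], truth) == (1.0, 0.0)
        assert score_recovery([], truth) == (0.0, 0.0)

    def test_partial_recovery_arithmetic(self):
        truth = self._truth([(f"s{i}", f"g{i}") for i in range(10)])
        called = [(f"s{i}", f"g{i}") for i in range(8)] + [("x1", "y1"), ("x2", "y2")]
        sens, fdp = score_recovery(called, truth)
        assert sens == pytest.approx(0.8)
        assert fdp == pytest.approx(0.2)


class TestRecoveryMonotonicity:
    """Sensitivity rises with coupling beta and falls with noise."""

    def _sens(self, beta, sigma, seed=13):
        cfg = SimulationConfig(seed=seed, n_lines_per_genotype=6,
                               n_planted_circuits=15, circuit_beta=beta,
                               noise_sd=sigma, n_mrna=400, n_lncrna=200,
                               n_circrna=120, n_mirnas=300)
        sens, _, _, _ = recover_circuits(cfg)
        return sens

    def test_beta_sweep_non_decreasing(self):
        sweep = [self._sens(b, 0.3) for b in (0.0, 0.45, 0.9)]
        assert all(a <= b + 1e-9 for a, b in zip(sweep, sweep[1:]))

    def test_noise_sweep_non_increasing(self):
        sweep = [self._sens(0.9, s) for s in (0.0, 0.6, 1.5)]
        assert all(a >= b - 1e-9 for a, b in zip(sweep, sweep[1:]))

    def test_zero_beta_recovery_at_chance_level(self):
        """With no coupling, recovery cannot beat a permutation baseline."""
        cfg = SimulationConfig(seed=21, n_lines_per_genotype=6,
                               n_planted_circuits=15, circuit_beta=0.0,
                               noise_sd=0.3, n_mrna=400, n_lncrna=200,
                               n_circrna=120, n_mirnas=300)
        sens, _, circuits, bundle = recover_circuits(cfg)
        # permutation baseline: relabel planted pairs among called pairs
        rng = np.random.default_rng(0)
        called = [c.pair for c in circuits]
        planted_sponges = [c["sponge_id"] for c in bundle.truth.circuits]
        planted_mrnas = [c["mrna_id"] for c in bundle.truth.circuits]
        baseline = []
        for _ in range(200):
            fake = set(zip(rng.permutation(planted_sponges),
                           rng.permutation(planted_mrnas)))
            baseline.append(len(fake & set(called)) / len(fake))
        assert sens <= np.quantile(baseline, 0.99) + 1e-9
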