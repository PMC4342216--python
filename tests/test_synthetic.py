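import numpy as np
import pytest
from scipy import stats

from fuzzygrade import SimulationConfig, make_two_platform_pair, simulate_cohort


class TestSimulateCohort:
    def test_shapes_counts_and_truth(self, default_cohort):
        expr, labels, truth, cfg = default_cohort
        assert expr.shape == (cfg.n_informative + cfg.n_noise,
                              cfg.n_grade1 + cfg.n_grade3 + cfg.n_grade2)
        assert labels["grade"].value_counts().to_dict() == {
            "1": cfg.n_grade1, "3": cfg.n_grade3, "2": cfg.n_grade2
        }
        assert len(truth.informative_probes) == cfg.n_informative
        assert set(truth.informative_probes) <= set(expr.index)
        assert set(truth.grade2_archetype.index) == set(
            labels.index[labels["grade"] == "2"]
        )

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_grade1=10, n_grade3=10, n_grade2=6,
                               n_informative=5, n_noise=20, seed=3)
        e1, l1, t1 = simulate_cohort(cfg)
        e2, l2, t2 = simulate_cohort(cfg)
        assert e1.equals(e2) and l1.equals(l2)
        assert np.array_equal(t1.informative_probes, t2.informative_probes)
        assert t1.grade2_archetype.equals(t2.grade2_archetype)

    def test_planted_shift_matches_effect_within_3se(self, default_cohort):
        expr, labels, truth, cfg = default_cohort
        g = labels["grade"]
        inf = expr.loc[truth.informative_probes]
        d = (inf.loc[:, (g == "3").to_numpy()].mean(axis=1)
             - inf.loc[:, (g == "1").to_numpy()].mean(axis=1))
        se = cfg.noise_sd * np.sqrt(1 / cfg.n_grade1 + 1 / cfg.n_grade3)
        target = cfg.effect * cfg.noise_sd
        assert np.all(np.abs(d - target) <= 3 * se)

    def test_noise_probe_t_stats_are_null(self, default_cohort):
        expr, labels, truth, cfg = default_cohort
        g = labels["grade"]
        noise = expr.drop(index=truth.informative_probes)
        t, _ = stats.ttest_ind(
            noise.loc[:, (g == "1").to_numpy()], noise.loc[:, (g == "3").to_numpy()],
            axis=1,
        )
        df = cfg.n_grade1 + cfg.n_grade3 - 2
        _, p = stats.kstest(t, stats.t(df).cdf)
        assert p > 0.01

    def test_zero_effect_removes_separation(self):
        cfg = SimulationConfig(n_grade1=30, n_grade3=30, n_grade2=5,
                               n_informative=10, n_noise=90, effect=0.0, seed=9)
        expr, labels, truth = simulate_cohort(cfg)
        g = labels["grade"]
        inf = expr.loc[truth.informative_probes]
        t, _ = stats.ttest_ind(
            inf.loc[:, (g == "1").to_numpy()], inf.loc[:, (g == "3").to_numpy()], axis=1
        )
        assert np.abs(t).max() < 4.0  # indistinguishable from noise

    def test_grade2_archetype_fraction_tracks_mix(self):
        fracs = []
        for seed in range(8):
            cfg = SimulationConfig(n_grade1=6, n_grade3=6, n_grade2=50,
                                   n_informative=4, n_noise=10,
                                   grade2_mix=0.3, seed=seed)
            _, _, truth = simulate_cohort(cfg)
            fracs.append((truth.grade2_archetype == "3").mean())
        assert np.mean(fracs) == pytest.approx(0.3, abs=0.07)

    def test_midpoint_samples_sit_between_archetypes(self):
        cfg = SimulationConfig(n_grade1=40, n_grade3=40, n_grade2=40,
                               n_informative=30, n_noise=10,
                               equivocal_fraction=1.0, noise_sd=0.1,
                               effect=20.0, seed=4)
        expr, labels, truth = simulate_cohort(cfg)
        g = labels["grade"]
        inf = expr.loc[truth.informative_probes]
        m1 = inf.loc[:, (g == "1").to_numpy()].mean(axis=1)
        m3 = inf.loc[:, (g == "3").to_numpy()].mean(axis=1)
        m2 = inf.loc[:, (g == "2").to_numpy()].mean(axis=1)
        assert np.allclose(m2, (m1 + m3) / 2, atol=0.2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_grade1=0)
        with pytest.raises(ValueError):
            SimulationConfig(grade2_mix=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(effect=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=0.0)


class TestTwoPlatformPair:
    def test_single_probe_zero_distortion_is_identity_up_to_namespace(self):
        cfg = SimulationConfig(n_grade1=8, n_grade3=8, n_grade2=4,
                               n_informative=5, n_noise=15, seed=6)
        pair = make_two_platform_pair(cfg, probes_per_gene=1, jitter_max=0.0)
        assert np.allclose(pair.expr1.to_numpy(), pair.expr2.to_numpy())
        assert list(pair.expr1.columns) == list(pair.expr2.columns)
        genes1 = [pair.probe_to_gene[p] for p in pair.expr1.index]
        genes2 = [pair.probe_to_gene[p] for p in pair.expr2.index]
        assert genes1 == genes2

    def test_probes_per_gene_namespace(self):
        cfg = SimulationConfig(n_grade1=8, n_grade3=8, n_grade2=2,
                               n_informative=3, n_noise=7, seed=6)
        pair = make_two_platform_pair(cfg, probes_per_gene=9)
        assert pair.expr2.shape[0] == 9 * pair.expr1.shape[0]
        assert not set(pair.expr1.index) & set(pair.expr2.index)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_grade1=8, n_grade3=8, n_grade2=2,
                               n_informative=3, n_noise=7, seed=13)
        a = make_two_platform_pair(cfg, probes_per_gene=3)
        b = make_two_platform_pair(cfg, probes_per_gene=3)
        assert a.expr2.equals(b.expr2)

    def test_noisier_probes_get_lower_membas_weight(self):
        from fuzzygrade import rank_probes, split_cohort

        cfg = SimulationConfig(n_grade1=40, n_grade3=40, n_grade2=2,
                               n_informative=20, n_noise=5, effect=2.0, seed=14)
        pair = make_two_platform_pair(cfg, probes_per_gene=6, jitter_max=3.0)
        te, tl, _, _ = split_cohort(pair.expr2, pair.labels)
        w = rank_probes(te, tl, "binomial")
        inf_genes = {g.replace("P1_", "") for g in pair.truth.informative_probes}
        keep = [i for i, p in enumerate(w.probe_ids)
                if pair.probe_to_gene[p] in inf_genes]
        weights = w.weights[keep]
        jit = pair.probe_jitter.loc[w.probe_ids[keep]].to_numpy()
        rho = stats.spearmanr(jit, weights).statistic
        assert rho < -0.3  # heavier jitter, smaller weight
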