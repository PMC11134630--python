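"""Synthetic-data generators: distributional structure, limits,
reproducibility."""

import numpy as np
import pytest

import evoisol as ev


def mean_q(preference, n_sims, seed, n_flies=50, max_pairs=25):
    cfg = ev.SimConfig(seed=seed, preference=preference,
                       n_flies_per_pop_per_sex=n_flies, max_pairs=max_pairs)
    rng = np.random.default_rng(seed)
    qs = []
    for _ in range(n_sims):
        t = ev.simulate_choice_assay(cfg, rng=rng)
        a, d = t.homotypic
        b, c = t.heterotypic
        if a * d + b * c > 0:
            qs.append((a * d - b * c) / (a * d + b * c))
    return np.mean(qs), np.std(qs) / np.sqrt(len(qs))


def oracle_mean_q(preference, n_sims, seed, n_flies=50, max_pairs=25):
    """Independent straightforward re-implementation of the sampling
    scheme: explicit fly lists, direct weighted draws."""
    rng = np.random.default_rng(seed)
    qs = []
    for _ in range(n_sims):
        females = ["A"] * n_flies + ["B"] * n_flies
        males = ["A"] * n_flies + ["B"] * n_flies
        counts = {("A", "A"): 0, ("A", "B"): 0, ("B", "A"): 0, ("B", "B"): 0}
        for _ in range(max_pairs):
            if not females or not males:
                break
            f = females.pop(rng.integers(len(females)))
            w = np.array([preference if m == f else 1.0 for m in males])
            mi = rng.choice(len(males), p=w / w.sum())
            m = males.pop(mi)
            counts[(f, m)] += 1
        a, d = counts[("A", "A")], counts[("B", "B")]
        b, c = counts[("A", "B")], counts[("B", "A")]
        if a * d + b * c > 0:
            qs.append((a * d - b * c) / (a * d + b * c))
    return np.mean(qs), np.std(qs) / np.sqrt(len(qs))


class TestChoiceAssay:
    def test_empty_assay_rejected(self):
        with pytest.raises(ValueError, match="empty assay"):
            ev.simulate_choice_assay(
                ev.SimConfig(seed=1, n_flies_per_pop_per_sex=0))

    def test_random_mating_mean_q_near_zero(self):
        q, se = mean_q(1.0, 800, seed=2)
        assert abs(q) < max(3 * se, 0.03)

    def test_infinite_preference_all_homotypic(self):
        cfg = ev.SimConfig(seed=3, preference=1e12)
        t = ev.simulate_choice_assay(cfg)
        assert sum(t.heterotypic) == 0
        assert ev.yules_index(t, "Q") == 1.0

    def test_matches_independent_resimulation(self):
        # E[Q] under preference 4: module vs independent oracle within
        # 2 combined MC standard errors
        q1, se1 = mean_q(4.0, 2500, seed=4)
        q2, se2 = oracle_mean_q(4.0, 2500, seed=104)
        assert abs(q1 - q2) < 2 * np.hypot(se1, se2)

    def test_monotone_in_preference(self):
        qs = [mean_q(p, 1200, seed=5)[0] for p in (1.0, 2.0, 4.0, 8.0)]
        assert all(b > a for a, b in zip(qs, qs[1:]))

    def test_stops_at_max_pairs(self):
        t = ev.simulate_choice_assay(ev.SimConfig(seed=6, max_pairs=10))
        assert t.total == 10


class TestChcGenerator:
    def test_closure_property(self):
        profiles = ev.simulate_chc(ev.SimConfig(seed=7), 5)
        for p in profiles:
            assert p.abundances.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p.abundances >= 0).all()

    def test_zero_effects_zero_noise_degenerate(self):
        cfg = ev.SimConfig(seed=8, sex_effect=np.zeros(12),
                           evo_effect=np.zeros(12), chc_noise_sd=0.0)
        profiles = ev.simulate_chc(cfg, 4)
        tab = ev.profiles_to_frame(profiles)
        res = ev.pca(ev.clr(tab.to_numpy()))
        assert res.degenerate

    def test_dominant_sex_effect_on_pc1(self):
        cfg = ev.SimConfig(seed=9)
        profiles = ev.simulate_chc(cfg, 12)
        tab = ev.profiles_to_frame(profiles)
        clr_vals = ev.clr(tab.to_numpy())
        res = ev.pca(clr_vals)
        # PC1 loading direction aligns with the injected sex contrast
        sex_dir = ev.clr(np.exp(cfg.chc_base_log + cfg.sex_effect)) - \
            ev.clr(np.exp(cfg.chc_base_log))
        cos = np.dot(res.loadings[:, 0], sex_dir) / (
            np.linalg.norm(res.loadings[:, 0]) * np.linalg.norm(sex_dir))
        assert abs(cos) > 0.95

    def test_minimum_compounds(self):
        with pytest.raises(ValueError):
            ev.simulate_chc(ev.SimConfig(seed=10, n_compounds=2,
                                         sex_effect=np.zeros(2),
                                         evo_effect=np.zeros(2),
                                         chc_base_log=np.zeros(2)), 3)


class TestDiallelGenerator:
    def test_design_arithmetic(self):
        sheet = ev.simulate_diallel(ev.SimConfig(seed=11), n_pops=3,
                                    n_vials=5)
        assert len(sheet) == 45
        assert sheet.groupby(["sire_pop", "dam_pop"]).size().eq(5).all()

    def test_no_advantage_equal_means(self):
        cfg = ev.SimConfig(seed=12, diallel_within_advantage=0.0)
        sheet = ev.simulate_diallel(cfg, n_pops=3, n_vials=3000)
        res = ev.cross_type_means(sheet)
        assert abs(res.deficit) < 0.02

    def test_deficit_converges_to_closed_form(self):
        # advantage 0.09 => between deficit -> 1 - 1/1.09 ~ 8.26%
        cfg = ev.SimConfig(seed=13, diallel_within_advantage=0.09)
        sheet = ev.simulate_diallel(cfg, n_pops=3, n_vials=5000)
        res = ev.cross_type_means(sheet)
        assert -res.deficit == pytest.approx(1 - 1 / 1.09, abs=0.01)

    def test_too_few_pops_rejected(self):
        with pytest.raises(ValueError):
            ev.simulate_diallel(ev.SimConfig(seed=14), n_pops=1)

    def test_poisson_moments(self):
        cfg = ev.SimConfig(seed=15, diallel_within_advantage=0.0,
                           diallel_mean=24.0)
        sheet = ev.simulate_diallel(cfg, n_pops=2, n_vials=20000)
        x = sheet["progeny_count"].to_numpy()
        assert x.mean() == pytest.approx(24.0, rel=0.01)
        assert x.var() == pytest.approx(24.0, rel=0.03)


class TestCountsGenerator:
    def test_counts_are_nonnegative_integers(self, small_counts):
        arr = small_counts.matrix.counts.to_numpy()
        assert np.issubdtype(arr.dtype, np.integer)
        assert (arr >= 0).all()

    def test_up_bias_one_all_up(self):
        cfg = ev.SimConfig(seed=16, n_genes=400, up_bias=1.0)
        sim = ev.simulate_counts(cfg, 2)
        assert (sim.truth["log2fc"] > 0).all()

    def test_shifts_confined_to_reproduction_set(self, small_counts):
        assert set(small_counts.truth.gene) <= set(
            small_counts.reproduction_set.genes)
        per_gene = small_counts.truth.groupby("gene").size()
        assert per_gene.isin([1, 2]).all()

    def test_nb_moments(self):
        # one gene, many samples: variance ~ mu + phi mu^2
        cfg = ev.SimConfig(seed=17, n_genes=5, nb_dispersion=0.2,
                           shared_lfc_sd=0.0, replicate_lfc_sd=0.0,
                           library_size_log_sd=0.0, n_replicates=2)
        sim = ev.simulate_counts(cfg, 2000)
        ev_m = sim.matrix.evolved()
        y = ev_m.counts.to_numpy(float)
        mu = y.mean(axis=1)
        var = y.var(axis=1)
        expect = mu + 0.2 * mu ** 2
        assert np.allclose(var, expect, rtol=0.15)

    def test_non_integer_n_genes_rejected(self):
        cfg = ev.SimConfig(seed=18)
        cfg.n_genes = 10.5
        with pytest.raises(ValueError):
            ev.simulate_counts(cfg, 2)


class TestReproducibility:
    def test_seeded_runs_bit_identical(self):
        for build in (
            lambda s: ev.simulate_choice_assay(ev.SimConfig(seed=s)).counts,
            lambda s: ev.profiles_to_frame(
                ev.simulate_chc(ev.SimConfig(seed=s), 4)).to_numpy(),
            lambda s: ev.simulate_diallel(
                ev.SimConfig(seed=s))["progeny_count"].to_numpy(),
            lambda s: ev.simulate_counts(
                ev.SimConfig(seed=s, n_genes=50), 2).matrix.counts.to_numpy(),
        ):
            a, b = build(123), build(123)
            assert np.array_equal(a, b)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ev.SimConfig(seed=1, preference=0.5)
        with pytest.raises(ValueError):
            ev.SimConfig(seed=1, up_bias=0.2)
        with pytest.raises(ValueError):
            ev.SimConfig(seed=1, sex_effect=np.zeros(5))
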