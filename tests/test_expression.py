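"""NB-GLM replicate-divergence machinery: CPM filter, dispersion
estimation, LRT, per-replicate change attribution, BH."""

import numpy as np
import pandas as pd
import pytest

import evoisol as ev
from evoisol.expression import CountMatrix


def matrix_from_arrays(counts, lib, reps, groups):
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        library_sizes=pd.Series(lib, index=samples),
        sample_meta=pd.DataFrame({"replicate": reps, "group": groups},
                                 index=samples))


class TestCpmFilter:
    def test_cpm_arithmetic(self):
        m = matrix_from_arrays(np.array([[100, 100]]), [2e6, 2e6],
                               ["R1", "R1"], ["evolved"] * 2)
        assert np.allclose(m.cpm().to_numpy(), 50.0)

    def test_zero_count_sample_removes_gene(self):
        counts = np.array([[5, 0], [5, 5]])
        m = matrix_from_arrays(counts, [1e6, 1e6], ["R1", "R1"],
                               ["evolved"] * 2)
        kept = ev.cpm_filter(m, 0.1)
        assert kept.gene_ids == ["g1"]

    def test_matches_brute_force(self, rng):
        counts = rng.poisson(0.3, size=(50, 8))
        lib = rng.uniform(0.5e6, 2e6, 8)
        m = matrix_from_arrays(counts, lib, ["R1"] * 8, ["evolved"] * 8)
        kept = set(ev.cpm_filter(m, 0.1).gene_ids)
        brute = {f"g{i}" for i in range(50)
                 if all(counts[i, j] / lib[j] * 1e6 > 0.1 for j in range(8))}
        assert kept == brute

    def test_negative_threshold_rejected(self, small_counts):
        with pytest.raises(ValueError):
            ev.cpm_filter(small_counts.matrix, -1)


class TestDispersion:
    def test_poisson_data_phi_near_zero(self):
        cfg = ev.SimConfig(seed=8, n_genes=100, nb_dispersion=0.0,
                           replicate_lfc_sd=0.0, n_replicates=10)
        sim = ev.simulate_counts(cfg, 20)  # 200 samples
        disp = ev.estimate_dispersion(sim.matrix.evolved())
        assert disp.common <= 0.01

    def test_nb_dispersion_recovered(self):
        cfg = ev.SimConfig(seed=9, n_genes=50, nb_dispersion=0.2,
                           replicate_lfc_sd=0.0, n_replicates=4)
        sim = ev.simulate_counts(cfg, 5)  # 20 evolved samples, 50 genes
        disp = ev.estimate_dispersion(sim.matrix.evolved())
        assert 0.1 <= np.median(disp.shrunken) <= 0.3

    def test_constant_counts_zero_dispersion(self):
        counts = np.full((5, 8), 40)
        m = matrix_from_arrays(counts, [1e6] * 8, ["R1"] * 4 + ["R2"] * 4,
                               ["evolved"] * 8)
        disp = ev.estimate_dispersion(m)
        assert disp.common == pytest.approx(0.0, abs=1e-4)
        assert np.all(disp.per_gene == 0)


class TestDivergenceLRT:
    def test_power_single_shifted_replicate(self):
        # each gene shifted 4-fold in one replicate, phi=0.05, n=3/replicate
        cfg = ev.SimConfig(seed=10, n_genes=300, nb_dispersion=0.05,
                           replicate_lfc_sd=2.0, shared_lfc_sd=0.0,
                           frac_reproduction_genes=0.5)
        sim = ev.simulate_counts(cfg, 3)
        div = ev.divergence_lrt(sim.matrix, 0.05)
        shifted = set(sim.truth.gene)
        tab = div.table.set_index("gene")
        detected = (tab.loc[list(shifted), "q"] < 0.05).mean()
        assert detected > 0.9

    def test_library_scale_invariance(self, small_counts):
        m = small_counts.matrix
        scaled = CountMatrix(m.counts, m.library_sizes * 7.0, m.sample_meta)
        p1 = ev.divergence_lrt(m, 0.2).table["p"]
        p2 = ev.divergence_lrt(scaled, 0.2).table["p"]
        assert np.allclose(p1, p2, atol=1e-8)

    def test_sample_reordering_invariance(self, small_counts):
        m = small_counts.matrix
        perm = np.random.default_rng(3).permutation(m.counts.shape[1])
        cols = m.counts.columns[perm]
        m2 = CountMatrix(m.counts[cols], m.library_sizes[cols],
                         m.sample_meta.loc[cols])
        p1 = ev.divergence_lrt(m, 0.2).table.set_index("gene")["p"]
        p2 = ev.divergence_lrt(m2, 0.2).table.set_index("gene")["p"]
        assert np.allclose(p1, p2.loc[p1.index], atol=1e-8)

    def test_requires_replicated_samples(self):
        m = matrix_from_arrays(np.ones((3, 2), dtype=int), [1e6, 1e6],
                               ["R1", "R2"], ["evolved"] * 2)
        with pytest.raises(ValueError):
            ev.divergence_lrt(m)


class TestPerReplicateChange:
    def test_identical_means_zero_lfc(self):
        counts = np.full((4, 12), 100)
        m = matrix_from_arrays(
            counts, [1e6] * 12,
            ["anc"] * 4 + ["R1"] * 4 + ["R2"] * 4,
            ["ancestral"] * 4 + ["evolved"] * 8)
        res = ev.per_replicate_change(m, 0.1)
        assert np.allclose(res.log2fc.to_numpy(), 0.0)
        assert (res.direction.to_numpy() == "none").all()

    def test_fourfold_ratio_with_vanishing_pseudocount(self):
        counts = np.array([[10, 10, 40, 40]])
        m = matrix_from_arrays(
            counts, [1e6] * 4, ["anc", "anc", "R1", "R1"],
            ["ancestral", "ancestral", "evolved", "evolved"])
        res = ev.per_replicate_change(m, 0.1, pseudocount=1e-9)
        assert res.log2fc.loc["g0", "R1"] == pytest.approx(2.0, abs=1e-6)

    def test_truth_recovery_sensitivity_and_fdr(self):
        cfg = ev.SimConfig(seed=21, n_genes=1000)
        sim = ev.simulate_counts(cfg, 5)
        filt = ev.cpm_filter(sim.matrix, 0.1)
        disp = ev.estimate_dispersion(filt.evolved())
        res = ev.per_replicate_change(filt, disp)
        truth_pairs = set(zip(sim.truth.gene, sim.truth.replicate))
        calls = res.direction
        tp = sum(1 for g, r in truth_pairs
                 if g in calls.index and calls.loc[g, r] != "none")
        n_calls = int((calls.to_numpy() != "none").sum())
        sensitivity = tp / len(truth_pairs)
        fdr = (n_calls - tp) / max(n_calls, 1)
        assert sensitivity > 0.8
        assert fdr < 0.1

    def test_requires_ancestral_samples(self):
        m = matrix_from_arrays(np.ones((2, 4), dtype=int), [1e6] * 4,
                               ["R1"] * 2 + ["R2"] * 2, ["evolved"] * 4)
        with pytest.raises(ValueError, match="ancestral"):
            ev.per_replicate_change(m, 0.1)


class TestBH:
    def test_step_up_fixture(self):
        q = ev.bh_adjust(np.array([0.01, 0.02, 0.04, 0.05]))
        assert np.allclose(q, [0.04, 0.04, 0.05, 0.05], atol=1e-12)

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.uniform(size=30))
        q = ev.bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_nan_passthrough(self):
        q = ev.bh_adjust(np.array([0.01, np.nan, 0.02]))
        assert np.isnan(q[1]) and not np.isnan(q[0])


def test_cpm_normalization_removes_library_offset():
    # samples with 10x library-size differences: genes without injected
    # replicate effects should show no divergence signal
    cfg = ev.SimConfig(seed=13, n_genes=200, replicate_lfc_sd=0.0,
                       library_size_log_sd=0.0, n_replicates=5)
    sim = ev.simulate_counts(cfg, 4)
    m = sim.matrix
    lib = m.library_sizes.copy()
    scale = np.where(np.arange(len(lib)) % 2 == 0, 10.0, 1.0)
    counts = (m.counts * scale).round().astype(int)
    m2 = CountMatrix(counts, lib * scale, m.sample_meta)
    cpm1 = m.cpm().to_numpy()
    cpm2 = m2.cpm().to_numpy()
    assert np.allclose(cpm1, cpm2, rtol=0.05, atol=1.0)
    div = ev.divergence_lrt(m2)
    assert (div.table["p"] < 0.05).mean() < 0.12
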