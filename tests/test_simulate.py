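"""Branching-process simulator: determinism, class structure, sequencing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cloneclock import (
    SimulationConfig,
    expected_class_spectrum,
    generate_benchmark_suite,
    net_growth_rate,
    sequence_tumor,
    simulate_lineage,
)
from cloneclock.simulate import UnreachableTargetError

LAM = net_growth_rate(0.2)


class TestSimulateLineage:
    def test_fixed_seed_reproducible(self, small_config):
        a = simulate_lineage(small_config, seed=5, tf=5, s=0.8, target_p=0.5)
        b = simulate_lineage(small_config, seed=5, tf=5, s=0.8, target_p=0.5)
        pd.testing.assert_frame_equal(a.mutations, b.mutations)
        assert a.params.te == b.params.te and a.params.P == b.params.P

    def test_neutral_tumor_has_no_subclone_classes(self, small_config):
        truth = simulate_lineage(small_config, seed=3, s=0.0)
        classes = set(truth.mutations.mutation_class)
        assert "branch" not in classes and "successive" not in classes
        assert truth.params.P == 0.0

    def test_trunk_count_matches_linear_accumulation(self, small_config):
        """Mean trunk count over replicates is mu*(tf-1): generations 1..3."""
        counts = []
        for rep in range(200):
            try:
                truth = simulate_lineage(small_config, seed=10_000 + rep, tf=4, s=0.8,
                                         target_p=0.5)
            except UnreachableTargetError:
                continue  # ancestral side extinct at emergence in this draw
            counts.append((truth.mutations.mutation_class == "trunk").sum())
        expected = 16.0 * 3
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 0.5

    def test_root_cohort_and_floor(self, small_config):
        truth = simulate_lineage(small_config, seed=11, tf=5, s=1.0, target_p=0.6)
        root = truth.mutations[truth.mutations.mutation_class == "root"]
        assert len(root) == small_config.n_root
        assert (root.cell_fraction == 1.0).all()
        assert (truth.mutations.cell_fraction >= small_config.fraction_floor).all()

    def test_unreachable_target_raises(self, small_config):
        # a tiny subclone fraction cannot be realized with early emergence:
        # the subclone is already a larger share of the tumor at birth
        with pytest.raises(UnreachableTargetError):
            simulate_lineage(small_config, seed=2, tf=4, s=0.5, target_p=0.005)

    def test_target_p_hits_exactly(self, small_config):
        truth = simulate_lineage(small_config, seed=21, tf=6, s=0.9, target_p=0.42)
        assert truth.params.P == pytest.approx(0.42, abs=1e-9)

    def test_fixed_size_mode(self):
        cfg = SimulationConfig(cutover_size=1500, target_size=1e6)
        truth = simulate_lineage(cfg, seed=8, tf=6, s=0.9)
        h = truth.handoff_generation
        ka, kf = truth.kf_census[h], truth.ka_census[h]
        # extrapolated census at te equals the target size
        d = truth.params.te - h
        m_f = LAM * (1 + truth.params.s)
        census = truth.ka_census[h] * math.exp(LAM * d) + truth.kf_census[h] * math.exp(m_f * d)
        assert census == pytest.approx(1e6, rel=1e-6)

    def test_ancestral_growth_rate_converges(self, small_config):
        """Realized log-census slope approaches ln(2(1-beta)) = ln 1.6."""
        slopes = []
        for rep in range(40):
            truth = simulate_lineage(small_config, seed=500 + rep, s=0.0)
            census = truth.ka_census
            gens = np.arange(len(census))
            sel = census > 0
            slope = np.polyfit(gens[sel][2:], np.log(census[sel][2:]), 1)[0]
            slopes.append(slope)
        assert np.mean(slopes) == pytest.approx(LAM, abs=0.05)

    def test_cohort_fractions_match_expected_spectrum(self, small_config):
        """Replicate-averaged trunk cohort fractions track fk(t).

        Early-generation shares are Jensen-inflated relative to the smooth
        expectation (E[1/N] > 1/E[N]), so the tolerance is loose.
        """
        sums = {1: [], 2: [], 3: []}
        for rep in range(100):
            try:
                truth = simulate_lineage(small_config, seed=3000 + rep, tf=4, s=0.8,
                                         target_p=0.5)
            except UnreachableTargetError:
                continue
            m = truth.mutations
            for g in sums:
                tr = m[(m.mutation_class == "trunk") & (m.generation == g)]
                if len(tr):
                    sums[g].append(tr.cell_fraction.iloc[0])
        spec = expected_class_spectrum(
            simulate_lineage(small_config, seed=1, tf=4, s=0.8, target_p=0.5).params
        )
        trunk = spec[spec.mutation_class == "trunk"].set_index("generation")
        for g in sums:
            assert np.mean(sums[g]) == pytest.approx(
                trunk.loc[float(g), "cell_fraction"], abs=0.06
            )

    def test_neutral_tail_law(self, small_config):
        """Pooled ancestral-tail counts follow N(>=u) ~ 0.94 mu (1-P)/(lam u).

        This is the generator-derived amplitude the inference model relies
        on; checked at a scaled fraction well below the lumpy top.
        """
        ratios = []
        for rep in range(15):
            truth = simulate_lineage(small_config, seed=7000 + rep, tf=6, s=0.8,
                                     target_p=0.5)
            m = truth.mutations
            P = truth.params.P
            u = 0.02 * (1 - P)
            obs = ((m.mutation_class == "incidental") & (m.cell_fraction >= u)).sum()
            pred = 0.94 * 16.0 * (1 - P) / (LAM * u)
            ratios.append(obs / pred)
        assert 0.75 < np.mean(ratios) < 1.25


class TestSequencing:
    @pytest.fixture(scope="class")
    def truth(self):
        return simulate_lineage(SimulationConfig(cutover_size=1500), seed=42, tf=5,
                                s=0.8, target_p=0.5)

    def test_read_count_invariants(self, truth):
        reads = sequence_tumor(truth, 120, 1.0, seed=1)
        assert (reads.alt_reads <= reads.depth).all()
        assert (reads.alt_reads >= 0).all()
        np.testing.assert_allclose(reads.vaf, reads.alt_reads / reads.depth)

    def test_root_vaf_centered_at_half(self, truth):
        reads = sequence_tumor(truth, 120, 1.0, seed=2)
        root = reads.merge(truth.mutations, on="mutation_id")
        root = root[root.mutation_class == "root"]
        se = math.sqrt(0.25 / 120 / len(root))
        assert abs(root.vaf.mean() - 0.5) < 3 * se

    def test_purity_halves_vaf(self, truth):
        reads = sequence_tumor(truth, 2000, 0.5, seed=3)
        root = reads.merge(truth.mutations, on="mutation_id")
        root = root[root.mutation_class == "root"]
        assert root.vaf.mean() == pytest.approx(0.25, abs=0.01)

    def test_deep_sequencing_recovers_fractions(self, truth):
        reads = sequence_tumor(truth, 10**6, 1.0, seed=4, fixed_depth=True)
        merged = reads.merge(truth.mutations, on="mutation_id")
        np.testing.assert_allclose(
            merged.vaf, merged.cell_fraction / 2.0, atol=1e-2
        )

    def test_alt_counts_binomial_goodness_of_fit(self, truth):
        """Marginal alt counts at fixed fraction pass a chi-square GOF test."""
        root = truth.mutations[truth.mutations.mutation_class == "root"]
        big = truth.__class__(params=truth.params,
                              mutations=pd.concat([root] * 40, ignore_index=True)
                              .assign(mutation_id=lambda d: range(len(d))))
        reads = sequence_tumor(big, 80, 1.0, seed=5, fixed_depth=True)
        obs = reads.alt_reads.to_numpy()
        edges = np.array([0, 32, 36, 40, 44, 48, 81])
        counts, _ = np.histogram(obs, bins=edges)
        probs = np.diff(stats.binom.cdf(edges - 1, 80, 0.5))
        probs[0] = stats.binom.cdf(edges[1] - 1, 80, 0.5)
        chi = stats.chisquare(counts, probs / probs.sum() * counts.sum())
        assert chi.pvalue > 0.001

    def test_bad_purity_rejected(self, truth):
        with pytest.raises(ValueError):
            sequence_tumor(truth, 120, 0.0, seed=1)


class TestBenchmarkSuite:
    def test_manifest_ranges_and_reproducibility(self):
        cfg = SimulationConfig(cutover_size=1200, target_size=1e6)
        tumors, manifest = generate_benchmark_suite(6, cfg, seed=9)
        assert len(manifest) == 6
        assert manifest.tf.between(4, 14).all()
        assert manifest.P.between(0.0, 0.97).all()
        _, manifest2 = generate_benchmark_suite(6, cfg, seed=9)
        pd.testing.assert_frame_equal(manifest, manifest2)

    def test_writes_files(self, tmp_path):
        cfg = SimulationConfig(cutover_size=1200, target_size=1e6)
        generate_benchmark_suite(2, cfg, seed=3, out_dir=tmp_path)
        assert (tmp_path / "manifest.tsv").exists()
        assert (tmp_path / "sim0000.variants.tsv").exists()
        assert (tmp_path / "sim0001.truth.tsv").exists()
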