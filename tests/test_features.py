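"""Featurization: XOR/XNOR partition, windowed SFS tensor, VCF path."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coaltrace import features, io, scenarios
from coaltrace.features import (MutationContextTensor, WindowScheme,
                                accessibility_channel, featurize_pair, from_vcf,
                                pivot_site_features, window_tensor)


class TestSiteFeatures:
    def test_hand_worked_toy_matrix(self):
        """4 haplotypes, 2 sites, pivot (0,1): xor/xnor/freq by enumeration."""
        G = np.array([[0, 1], [1, 1], [0, 0], [0, 1]])
        sf = pivot_site_features(G, (0, 1))
        assert sf.xor.tolist() == [1, 0]
        assert sf.xnor.tolist() == [0, 1]
        assert sf.freq_class.tolist() == [0, 1]

    def test_identical_pivot_haplotypes_all_xnor(self):
        G = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 0]])
        sf = pivot_site_features(G, (0, 1))
        assert sf.xor.sum() == 0

    def test_nonpivot_permutation_invariance(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 2, size=(10, 30))
        sf = pivot_site_features(G, (0, 1))
        Gp = G.copy()
        Gp[2:] = Gp[2:][rng.permutation(8)]
        sfp = pivot_site_features(Gp, (0, 1))
        assert np.array_equal(sf.freq_class, sfp.freq_class)
        assert np.array_equal(sf.xor, sfp.xor)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            pivot_site_features(np.array([[0, 2], [1, 0]]), (0, 1))

    def test_folded_classes_reflect(self):
        G = np.zeros((6, 1), dtype=int)
        G[2:5, 0] = 1  # 3 of 4 non-pivot carriers
        sf = pivot_site_features(G, (0, 1), folded=True)
        assert sf.freq_class[0] == 1  # min(3, 4-3)


class TestWindowTensor:
    def test_empty_sites_give_zero_tensor(self):
        scheme = WindowScheme(seq_length=10_000, window_bp=2_000, n_freq=5)
        sf = pivot_site_features(np.zeros((4, 0), dtype=int), (0, 1))
        mc = window_tensor(sf, np.zeros(0), scheme)
        assert mc.counts.sum() == 0

    def test_base_scale_matches_brute_force_window_counts(self, small_rep,
                                                          small_scheme):
        """Summing (Z, N) at the base scale = direct per-window site count."""
        sf = pivot_site_features(small_rep.genotypes, (2, 3))
        mc = window_tensor(sf, small_rep.positions, small_scheme)
        w = small_scheme.window_bp
        brute = np.histogram(small_rep.positions,
                             bins=np.arange(0, small_scheme.seq_length + w, w))[0]
        assert np.array_equal(mc.counts[:, 0].sum(axis=(0, 2)), brute)

    def test_partition_conservation_exact(self, small_rep, small_scheme):
        """XOR-channel SFS + XNOR-channel SFS = total windowed SFS."""
        sf = pivot_site_features(small_rep.genotypes, (0, 1))
        mc = window_tensor(sf, small_rep.positions, small_scheme)
        total = mc.counts.sum(axis=0)  # (WS, K, N)
        # brute-force total SFS per base window
        w = small_scheme.window_bp
        widx = (small_rep.positions // w).astype(int)
        brute = np.zeros((small_scheme.n_windows, small_scheme.n_freq), dtype=int)
        np.add.at(brute, (widx, np.minimum(sf.freq_class, small_scheme.n_freq - 1)), 1)
        assert np.array_equal(total[0], brute)

    def test_pivot_swap_symmetry(self, small_rep, small_scheme):
        mc1 = featurize_pair(small_rep.genotypes, small_rep.positions, (4, 5),
                             small_scheme)
        mc2 = featurize_pair(small_rep.genotypes, small_rep.positions, (5, 4),
                             small_scheme)
        assert np.array_equal(mc1.counts, mc2.counts)

    def test_wider_scales_hold_more_sites(self, small_rep, small_scheme):
        sf = pivot_site_features(small_rep.genotypes, (0, 1))
        mc = window_tensor(sf, small_rep.positions, small_scheme)
        per_scale = mc.counts.sum(axis=(0, 2, 3)).astype(float)
        assert np.all(np.diff(per_scale) > 0)  # 2x span => ~2x sites
        # interior windows away from edges: doubling span ~doubles counts
        interior = slice(20, 30)
        s0 = mc.counts[:, 0, interior].sum()
        s1 = mc.counts[:, 1, interior].sum()
        assert s1 / s0 == pytest.approx(2.0, rel=0.35)

    def test_density_normalizes_by_span(self, small_rep, small_scheme):
        sf = pivot_site_features(small_rep.genotypes, (0, 1))
        mc = window_tensor(sf, small_rep.positions, small_scheme)
        spans_kb = np.array(small_scheme.scale_multipliers) * \
            small_scheme.window_bp / 1000
        manual = mc.counts[0, 3] / spans_kb[3]
        assert np.allclose(mc.density[0, 3], manual)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_phase_invariance_for_within_individual_pivots(self, seed):
        """Randomly re-phasing het sites leaves the tensor unchanged."""
        rng = np.random.default_rng(seed)
        G = rng.integers(0, 2, size=(8, 40))
        pos = np.sort(rng.choice(20_000, size=40, replace=False)).astype(float)
        scheme = WindowScheme(seq_length=20_000, window_bp=2_000, n_freq=7)
        mc = featurize_pair(G, pos, (0, 1), scheme)
        het = G[0] != G[1]
        flip = het & (rng.random(40) < 0.5)
        Gf = G.copy()
        Gf[0, flip], Gf[1, flip] = G[1, flip], G[0, flip]
        mcf = featurize_pair(Gf, pos, (0, 1), scheme)
        assert np.array_equal(mc.counts, mcf.counts)
        assert mc.xor_total == mcf.xor_total


class TestAccessibility:
    def test_empty_mask_zero_everywhere_except_edges(self):
        scheme = WindowScheme(seq_length=20_000, window_bp=2_000, n_freq=5)
        frac = accessibility_channel(None, scheme)
        assert np.all(frac[0] == 0)  # base scale fits inside the sequence
        assert frac[-1].max() > 0  # widest scale truncated at the edges

    def test_fully_and_half_masked_windows(self):
        scheme = WindowScheme(seq_length=20_000, window_bp=2_000,
                              scale_multipliers=(1,), n_freq=5)
        frac = accessibility_channel(np.array([[2000., 4000.], [6000., 7000.]]),
                                     scheme)
        assert frac[0, 1] == pytest.approx(1.0)  # window [2000, 4000) fully masked
        assert frac[0, 3] == pytest.approx(0.5)  # window [6000, 8000) half masked
        assert frac[0, 0] == 0.0

    def test_masked_window_has_no_sites(self, small_rep):
        masked = scenarios.apply_accessibility(small_rep,
                                               np.array([[10_000., 12_000.]]))
        in_window = (masked.positions >= 10_000) & (masked.positions < 12_000)
        assert in_window.sum() == 0

    def test_bad_masks_rejected(self):
        scheme = WindowScheme(seq_length=10_000, window_bp=2_000, n_freq=5)
        with pytest.raises(ValueError):
            accessibility_channel(np.array([[5_000., 4_000.]]), scheme)
        with pytest.raises(ValueError):
            accessibility_channel(np.array([[0., 4000.], [3000., 6000.]]), scheme)


class TestVcf:
    def test_simulated_vcf_roundtrips_to_identical_tensor(self, tmp_path):
        """Write a replicate as VCF, re-read, and compare tensors exactly."""
        cfg = scenarios.build_scenario("narrow_constant", seq_length=20_000,
                                       diploid_n=5)
        rep = scenarios.simulate(cfg, seed=7)
        path = tmp_path / "sim.vcf"
        io.write_vcf(rep, str(path))
        afs = [f"ind_{i}" for i in range(1, 5)]
        G, pos = from_vcf(str(path), "ind_0", afs)
        scheme = WindowScheme.for_cohort(cfg.seq_length, cfg.window_bp, 5)
        direct = featurize_pair(rep.genotypes, rep.positions, (0, 1), scheme)
        via_vcf = featurize_pair(G, pos, (0, 1), scheme)
        assert np.array_equal(direct.counts, via_vcf.counts)
        assert direct.xor_total == via_vcf.xor_total

    def test_het_genotype_is_xor_regardless_of_phase(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tf\ta\n"
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0|0\n"
            "1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/1\n")
        G, pos = from_vcf(str(path), "f", ["a"])
        sf = pivot_site_features(G, (0, 1))
        assert sf.xor.tolist() == [1, 0]  # het -> XOR; hom-alt -> XNOR
        assert sf.freq_class.tolist() == [0, 1]  # AFS carrier haplotypes
        assert pos.tolist() == [99.0, 199.0]  # 1-based -> 0-based

    def test_missing_sample_raises_and_empty_region_ok(self, tmp_path):
        cfg = scenarios.build_scenario("narrow_constant", seq_length=20_000,
                                       diploid_n=3)
        rep = scenarios.simulate(cfg, seed=9)
        path = tmp_path / "sim.vcf"
        io.write_vcf(rep, str(path))
        with pytest.raises(KeyError):
            from_vcf(str(path), "nope", ["ind_1"])
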