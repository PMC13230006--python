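import itertools

import numpy as np
import pytest

from retention_grammar import rbp_wavelet as rw
from retention_grammar.intervals import PWMRecord
from retention_grammar.synthetic_data import generate_pwms, plant_motifs, pwm_consensus


def uniform_pwm(k=7, name="U"):
    return PWMRecord(name, np.full((4, k), 0.25))


def brute_force_threshold(pwm):
    logp = np.log2(np.asarray(pwm.matrix) + rw.LOG_EPS)
    scores = sorted(
        sum(logp["ACGT".index(b), j] for j, b in enumerate(kmer))
        for kmer in map("".join, itertools.product("ACGT", repeat=pwm.k))
    )
    return scores[(len(scores) - 1) // 2]


class TestCalibrateThreshold:
    def test_uniform_pwm_degenerate_distribution(self):
        # every 7-mer scores 7*log2(0.25) ~ -14 (epsilon-shifted)
        thr = rw.calibrate_threshold(uniform_pwm())
        assert thr == pytest.approx(7 * np.log2(0.25 + rw.LOG_EPS))

    def test_k1_deterministic_pwm(self):
        pwm = PWMRecord("K1", np.array([[1.0], [0.0], [0.0], [0.0]]))
        # scores: {log2(1+eps), log2(eps) x3}; lower-middle of 4 = log2(eps)
        assert rw.calibrate_threshold(pwm) == pytest.approx(np.log2(rw.LOG_EPS))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.dirichlet(np.ones(4), size=5).T  # k=5 keeps the oracle fast
        pwm = PWMRecord("R", mat)
        assert rw.calibrate_threshold(pwm) == pytest.approx(
            brute_force_threshold(pwm), abs=1e-12
        )


class TestBinarize:
    def test_uniform_pwm_ties_never_pass(self):
        sig = rw.binarize("ACGTACGTACGT", uniform_pwm(), rw.calibrate_threshold(uniform_pwm()))
        assert not sig.x.any()

    def test_matches_per_window_scoring_oracle(self):
        rng = np.random.default_rng(5)
        mat = np.full((4, 7), 0.04)
        mat[0, :] = 0.88  # strongly prefers AAAAAAA
        pwm = PWMRecord("A7", mat)
        thr = rw.calibrate_threshold(pwm)
        seq = "AAAAAAACCCCCCC"
        sig = rw.binarize(seq, pwm, thr)
        scores = rw.score_windows(seq, pwm)
        expected = np.zeros(len(seq), dtype=np.int8)
        expected[: len(scores)] = scores > thr
        assert (sig.x == expected).all()
        assert sig.x[0] == 1 and sig.x.size == len(seq)

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            rw.binarize("ACG", uniform_pwm(), -10)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            rw.binarize("ACGTNACGTACG", uniform_pwm(), -10)


class TestMergeOr:
    def test_position_wise_or(self):
        a = rw.BindingSignal(np.array([0, 1, 0]), "X")
        b = rw.BindingSignal(np.array([1, 1, 0]), "X")
        assert (rw.merge_or([a, b]).x == [1, 1, 0]).all()

    def test_single_signal_unchanged(self):
        a = rw.BindingSignal(np.array([0, 1, 1]), "X")
        assert (rw.merge_or([a]).x == a.x).all()

    def test_length_mismatch_rejected(self):
        a = rw.BindingSignal(np.array([0, 1]), "X")
        b = rw.BindingSignal(np.array([0, 1, 0]), "X")
        with pytest.raises(ValueError):
            rw.merge_or([a, b])


from tests_oracle_helpers import direct_modwt as direct_modwt_oracle


class TestModwtHaar:
    def test_constant_signal_has_zero_detail(self):
        wc = rw.modwt_haar(np.full(11, 3.7), levels=4)
        for w in wc.w:
            assert np.allclose(w, 0)

    def test_unit_impulse_matches_filter_response(self):
        x = np.zeros(8)
        x[3] = 1.0
        wc = rw.modwt_haar(x, levels=2)
        oracle = direct_modwt_oracle(x, 2)
        for got, want in zip(wc.w, oracle):
            assert np.allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("N", [7, 16, 33])
    def test_equals_circular_convolution_oracle(self, N):
        rng = np.random.default_rng(N)
        for _ in range(10):
            x = rng.normal(size=N)
            wc = rw.modwt_haar(x, levels=4)
            for got, want in zip(wc.w, direct_modwt_oracle(x, 4)):
                assert np.abs(got - want).max() < 1e-10

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        shift = 7
        wc = rw.modwt_haar(x, 3)
        wc_shifted = rw.modwt_haar(np.roll(x, shift), 3)
        for a, b in zip(wc.w, wc_shifted.w):
            assert np.allclose(np.roll(a, shift), b, atol=1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            rw.modwt_haar(np.array([1.0]), 2)

    def test_every_level_keeps_input_length(self):
        wc = rw.modwt_haar(np.arange(13, dtype=float), levels=6)
        assert all(w.size == 13 for w in wc.w)


class TestDescriptors:
    def test_all_zero_coefficients_degenerate_conventions(self):
        wc = rw.WaveletCoefficients(w=[np.zeros(6), np.zeros(6)])
        d = rw.descriptors(wc)
        assert (d == 0).all().all()

    def test_single_spike_level(self):
        wc = rw.WaveletCoefficients(w=[np.array([0.0, 0, 0, 0, 10])])
        d = rw.descriptors(wc)
        assert d.loc[1, "E"] == pytest.approx(1.0)
        assert d.loc[1, "O"] == pytest.approx(0.2)
        assert d.loc[1, "S"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [1, 4, 9, 25])
    def test_flat_vector_sparsity_is_sqrt_n(self, n):
        wc = rw.WaveletCoefficients(w=[np.full(n, 2.5)])
        assert rw.descriptors(wc).loc[1, "S"] == pytest.approx(np.sqrt(n))

    def test_energies_sum_to_zero_or_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(4, 50)))
            d = rw.descriptors(rw.modwt_haar(x, 5))
            assert d["E"].sum() == pytest.approx(1.0)
        d0 = rw.descriptors(rw.modwt_haar(np.full(12, 2.0), 5))
        assert d0["E"].sum() == 0.0

    def test_descriptors_invariant_under_circular_shift(self):
        rng = np.random.default_rng(12)
        x = (rng.random(40) < 0.3).astype(float)
        d1 = rw.descriptors(rw.modwt_haar(x, 4))
        d2 = rw.descriptors(rw.modwt_haar(np.roll(x, 11), 4))
        assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)


class TestFeatureBlock:
    def test_column_count_is_three_levels_per_rbp(self):
        groups = generate_pwms(2, seed=1)
        feats = rw.rbp_feature_block("ACGT" * 40, groups, levels=2)
        assert len(feats) == 2 * 3 * 2
        assert "RBP001|E|L1" in feats.index

    def test_single_rbp_default_levels_gives_18(self):
        groups = generate_pwms(1, seed=1)
        feats = rw.rbp_feature_block("ACGT" * 40, groups, levels=6)
        assert len(feats) == 18

    def test_extractor_column_order_stable(self, tiny_study, tiny_catalog):
        ext = rw.RBPWaveletExtractor(
            genome=tiny_study.genome, pwm_groups=tiny_study.pwm_groups
        ).fit(tiny_catalog)
        df = ext.transform(tiny_catalog[:3])
        assert list(df.columns) == ext.feature_names_out_
        assert df.shape[1] == 18 * len(tiny_study.pwm_groups)


class TestPlantedStructureSeparation:
    def _descriptors_for(self, seq, pwm, thr):
        x = rw.binarize(seq, pwm, thr).x.astype(float)
        return rw.descriptors(rw.modwt_haar(x, 6))

    def test_denser_planted_signals_carry_more_wavelet_energy(self):
        """Constitutive-style plantings (denser, clustered) yield more
        total detail energy than retained-style plantings (sparser,
        scattered) after the full scan-binarize-transform pipeline."""
        groups = generate_pwms(1, seed=4, multi_fraction=0.0)
        pwm = groups["RBP001"][0]
        thr = rw.calibrate_threshold(pwm)
        base_rng = np.random.default_rng(100)
        e_diffs = []
        for _ in range(60):
            seq = "".join(base_rng.choice(list("ACGT"), size=600))
            ci_like = plant_motifs(
                seq, pwm, "clustered", 0.8, np.random.default_rng(base_rng.integers(1 << 30))
            )
            ri_like = plant_motifs(
                seq, pwm, "uniform", 0.3, np.random.default_rng(base_rng.integers(1 << 30))
            )
            x_ci = rw.binarize(ci_like, pwm, thr).x.astype(float)
            x_ri = rw.binarize(ri_like, pwm, thr).x.astype(float)
            e_ci = sum((w**2).sum() for w in rw.modwt_haar(x_ci, 6).w)
            e_ri = sum((w**2).sum() for w in rw.modwt_haar(x_ri, 6).w)
            e_diffs.append(e_ci - e_ri)
        assert np.mean(e_diffs) > 0

    def test_ci_style_occupancy_has_higher_coarse_sparsity_values(self):
        """On clean occupancy vectors, dense loosely-clustered signals
        (regulatory-hub geometry) show higher coarse-level L1/L2 values
        than sparse uniformly scattered signals — the direction that
        separates constitutive from retained intron binding profiles."""
        rng = np.random.default_rng(0)
        N = 600
        diffs = []
        for _ in range(100):
            ci = np.zeros(N)
            for center in rng.integers(0, N, size=5):  # 5 hubs x 12 sites
                for j in range(12):
                    ci[(center + j * 21) % N] = 1
            ri = np.zeros(N)
            ri[rng.choice(N, size=15, replace=False)] = 1
            d_ci = rw.descriptors(rw.modwt_haar(ci, 6))
            d_ri = rw.descriptors(rw.modwt_haar(ri, 6))
            diffs.append(
                (d_ci.loc[5, "S"] + d_ci.loc[6, "S"]) - (d_ri.loc[5, "S"] + d_ri.loc[6, "S"])
            )
        assert np.mean(diffs) > 0

    def test_equal_density_clustering_concentrates_coarse_coefficients(self):
        """At equal placement density, clustering alone concentrates the
        coarse-scale coefficients, lowering the L1/L2 ratio (lower =
        sparser); the class contrast above therefore requires the
        density difference as well."""
        groups = generate_pwms(1, seed=4, multi_fraction=0.0)
        pwm = groups["RBP001"][0]
        thr = rw.calibrate_threshold(pwm)
        base_rng = np.random.default_rng(200)
        diffs = []
        for _ in range(60):
            seq = "".join(base_rng.choice(list("ACGT"), size=600))
            clu = plant_motifs(seq, pwm, "clustered", 1.0, np.random.default_rng(base_rng.integers(1 << 30)))
            uni = plant_motifs(seq, pwm, "uniform", 1.0, np.random.default_rng(base_rng.integers(1 << 30)))
            d_clu = self._descriptors_for(clu, pwm, thr)
            d_uni = self._descriptors_for(uni, pwm, thr)
            diffs.append(
                (d_clu.loc[5, "S"] + d_clu.loc[6, "S"]) - (d_uni.loc[5, "S"] + d_uni.loc[6, "S"])
            )
        assert np.mean(diffs) < 0


def test_modwt_runtime_scales_linearly():
    """O(N*L): doubling N must not blow up runtime superlinearly."""
    import time

    rng = np.random.default_rng(0)
    times = []
    for N in (20_000, 40_000, 80_000):
        x = rng.normal(size=N)
        t0 = time.perf_counter()
        for _ in range(5):
            rw.modwt_haar(x, 6)
        times.append(time.perf_counter() - t0)
    # allow generous slack over the x4 expected for strict linearity
    assert times[2] < 10 * times[0] + 0.05
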