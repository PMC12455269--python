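import math

import numpy as np
import pytest
from scipy.stats import rankdata

from amyspace.map_metrics import (GradientTable, compute_falff, compute_reho,
                                  compute_wdece, fit_dti_wlls, fit_dti_volume,
                                  motion_screen)
from amyspace.synthgen import (default_gradient_table, generate_dwi_signals,
                               random_tensor_field)
from amyspace.volumes import MaskVolume, SeriesVolume


# ---------------------------------------------------------------------------
# independent oracles

def kendalls_w_oracle(ts: np.ndarray) -> float:
    """Direct evaluation of Kendall's W with mid-rank tie correction."""
    n, m = ts.shape
    ranks = np.array([rankdata(t) for t in ts])
    r_t = ranks.sum(axis=0)
    s = float(((r_t - r_t.mean()) ** 2).sum())
    t_corr = 0.0
    for t in ranks:
        _, counts = np.unique(t, return_counts=True)
        t_corr += float((counts.astype(float) ** 3 - counts).sum())
    return 12.0 * s / (n**2 * (m**3 - m) - n * t_corr)


def wdece_oracle(ts: np.ndarray, sparsity: float) -> np.ndarray:
    """Exhaustive all-pairs degree centrality over <= 20 voxels."""
    v = ts.shape[0]
    edges = []
    for i in range(v):
        for j in range(i + 1, v):
            r = np.corrcoef(ts[i], ts[j])[0, 1]
            if r > 0:
                edges.append((i, j, r))
    deg = np.zeros(v)
    if edges:
        k = math.ceil(sparsity * len(edges))
        edges.sort(key=lambda e: -e[2])
        for i, j, r in edges[:k]:
            deg[i] += r
            deg[j] += r
    return deg


def fa_oracle(lams) -> float:
    lam = np.asarray(lams, dtype=float)
    lbar = lam.mean()
    return math.sqrt(1.5) * math.sqrt(((lam - lbar) ** 2).sum()) / math.sqrt(
        (lam**2).sum())


# ---------------------------------------------------------------------------
# ReHo

class TestReHo:
    def _series(self, arr):
        return SeriesVolume(np.asarray(arr, dtype=float), tr=0.8)

    def test_identical_series_give_full_concordance(self):
        t = np.arange(10.0)
        vol = self._series(np.tile(t, (1, 1, 3, 1)))
        out = compute_reho(vol)
        np.testing.assert_allclose(out.data, 1.0)

    def test_reversed_rank_pair_gives_zero(self):
        vol = self._series(np.stack([np.arange(6.0), np.arange(6.0)[::-1]]
                                    ).reshape(1, 1, 2, 6))
        out = compute_reho(vol)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_direct_kendalls_w(self, seed):
        rng = np.random.default_rng(seed)
        n_vox, m = rng.integers(3, 6), rng.integers(4, 13)
        ts = rng.normal(size=(n_vox, m))
        if seed % 2:  # exercise the tie-correction path
            ts = np.round(ts)
        vol = self._series(ts.reshape(1, 1, n_vox, m))
        out = compute_reho(vol)
        # every voxel's truncated neighbourhood covers the full line of voxels
        # only when n_vox <= 3; check the centre voxel, whose 27-neighbourhood
        # spans voxels [c-1, c+1]
        c = n_vox // 2
        expected = kendalls_w_oracle(ts[max(0, c - 1):c + 2])
        assert out.data[0, 0, c] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        ts = rng.normal(size=(1, 1, 4, 12))
        a = compute_reho(SeriesVolume(ts, tr=1.0)).data
        b = compute_reho(SeriesVolume(np.exp(3 * ts) + 5, tr=1.0)).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_constant_neighbourhood_emits_zero(self):
        vol = self._series(np.ones((2, 2, 2, 8)))
        out = compute_reho(vol)
        np.testing.assert_allclose(out.data, 0.0)

    def test_neighbourhood_validation(self):
        vol = self._series(np.random.default_rng(0).normal(size=(2, 2, 2, 8)))
        with pytest.raises(ValueError, match="neighbourhood"):
            compute_reho(vol, neighbourhood=28)


# ---------------------------------------------------------------------------
# fALFF

class TestFalff:
    def _sinusoid(self, freq, n=488, tr=0.8, shape=(2, 2, 2)):
        t = np.arange(n) * tr
        wave = np.sin(2 * np.pi * freq * t)
        return SeriesVolume(np.broadcast_to(wave, shape + (n,)).copy(), tr=tr)

    def test_in_band_sinusoid(self):
        out = compute_falff(self._sinusoid(0.05))
        assert np.all(out.data >= 0.99)

    def test_out_of_band_sinusoid(self):
        out = compute_falff(self._sinusoid(0.3))
        assert np.all(out.data <= 0.05)

    def test_white_noise_matches_bin_fraction(self):
        n, tr = 488, 0.8
        freqs = np.fft.rfftfreq(n, tr)
        frac = ((freqs >= 0.01) & (freqs <= 0.1)).sum() / (freqs.size - 1)
        rng = np.random.default_rng(0)
        vol = SeriesVolume(rng.normal(size=(12, 12, 8, n)), tr=tr)
        out = compute_falff(vol)
        assert abs(out.data.mean() - frac) < 0.02

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(1)
        ts = rng.normal(size=(2, 2, 2, 64))
        a = compute_falff(SeriesVolume(ts, tr=0.8)).data
        b = compute_falff(SeriesVolume(1e4 * ts, tr=0.8)).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_band_validation(self):
        vol = self._sinusoid(0.05, n=64)
        with pytest.raises(ValueError, match="Nyquist"):
            compute_falff(vol, band=(0.01, 5.0))
        with pytest.raises(ValueError, match="no frequency bins"):
            compute_falff(SeriesVolume(np.zeros((1, 1, 1, 16)), tr=0.1),
                          band=(0.01, 0.1))


# ---------------------------------------------------------------------------
# wDeCe

class TestWdece:
    def test_identical_series_full_sparsity(self):
        n = 5
        ts = np.tile(np.sin(np.arange(30.0)), (n, 1))
        vol = SeriesVolume(ts.reshape(1, 1, n, 30), tr=1.0)
        mask = MaskVolume(np.ones((1, 1, n), dtype=bool))
        out = compute_wdece(vol, mask, sparsity=1.0)
        np.testing.assert_allclose(out.data[0, 0], n - 1, atol=1e-10)

    @pytest.mark.parametrize("seed,sparsity", [(0, 0.5), (1, 0.1), (2, 1.0),
                                               (3, 0.25)])
    def test_matches_brute_force(self, seed, sparsity):
        rng = np.random.default_rng(seed)
        v = int(rng.integers(4, 21))
        ts = rng.normal(size=(v, 40))
        vol = SeriesVolume(ts.reshape(1, 1, v, 40), tr=1.0)
        mask = MaskVolume(np.ones((1, 1, v), dtype=bool))
        out = compute_wdece(vol, mask, sparsity=sparsity)
        np.testing.assert_allclose(out.data[0, 0], wdece_oracle(ts, sparsity),
                                   atol=1e-10)

    def test_retained_edge_count_is_ceil(self):
        rng = np.random.default_rng(4)
        ts = rng.normal(size=(8, 40))
        corr = np.corrcoef(ts)
        iu, ju = np.triu_indices(8, k=1)
        n_pos = int((corr[iu, ju] > 0).sum())
        vol = SeriesVolume(ts.reshape(1, 1, 8, 40), tr=1.0)
        mask = MaskVolume(np.ones((1, 1, 8), dtype=bool))
        out = compute_wdece(vol, mask, sparsity=0.5)
        # total degree = 2 * (sum of the ceil(0.5 * n_pos) largest positive weights)
        k = math.ceil(0.5 * n_pos)
        kept = np.sort(corr[iu, ju][corr[iu, ju] > 0])[::-1][:k]
        assert out.data[0, 0].sum() == pytest.approx(2 * kept.sum(), abs=1e-10)

    def test_zero_variance_voxel_excluded(self):
        rng = np.random.default_rng(5)
        ts = rng.normal(size=(4, 30))
        ts[2] = 3.0  # constant voxel
        vol = SeriesVolume(ts.reshape(1, 1, 4, 30), tr=1.0)
        mask = MaskVolume(np.ones((1, 1, 4), dtype=bool))
        out = compute_wdece(vol, mask, sparsity=1.0)
        assert out.data[0, 0, 2] == 0.0


# ---------------------------------------------------------------------------
# DTI

class TestDTI:
    def test_isotropic_tensor(self):
        grads = default_gradient_table(0)
        d = np.eye(3) * 0.7e-3
        dwi = generate_dwi_signals(d.reshape(1, 1, 1, 3, 3), grads, s0=500.0)
        fit = fit_dti_wlls(dwi.data[0, 0, 0], grads)
        assert fit.md == pytest.approx(0.7e-3, abs=1e-12)
        assert fit.fa == pytest.approx(0.0, abs=1e-10)
        assert fit.s0 == pytest.approx(500.0, rel=1e-10)

    def test_prolate_tensor_matches_closed_form_fa(self):
        grads = default_gradient_table(1)
        lams = (1.7e-3, 0.3e-3, 0.3e-3)
        d = np.diag(lams)
        dwi = generate_dwi_signals(d.reshape(1, 1, 1, 3, 3), grads)
        fit = fit_dti_wlls(dwi.data[0, 0, 0], grads)
        assert fit.fa == pytest.approx(fa_oracle(lams), abs=1e-10)
        assert fa_oracle(lams) == pytest.approx(0.799, abs=5e-4)

    def test_noiseless_recovery_to_1e10(self):
        grads = default_gradient_table(2)
        tf = random_tensor_field((3, 3, 2), seed=3)
        dwi = generate_dwi_signals(tf, grads, s0=1000.0, noise_sd=0.0)
        flat = tf.reshape(-1, 3, 3)
        sig = dwi.data.reshape(-1, len(grads))
        for i in range(flat.shape[0]):
            fit = fit_dti_wlls(sig[i], grads)
            assert np.abs(fit.D - flat[i]).max() < 1e-10

    def test_reduces_to_ols_with_equal_weights(self):
        grads = default_gradient_table(4)
        rng = np.random.default_rng(4)
        sig = np.exp(rng.normal(6.0, 0.2, len(grads)))
        fit0 = fit_dti_wlls(sig, grads, iterations=0)
        X = grads.design_matrix()
        beta, *_ = np.linalg.lstsq(X, np.log(sig), rcond=None)
        assert fit0.s0 == pytest.approx(float(np.exp(beta[0])), rel=1e-9)

    def test_b0_signal_equals_s0(self):
        grads = GradientTable(bvals=np.zeros(7), bvecs=np.zeros((7, 3)))
        d = np.eye(3) * 1e-3
        dwi = generate_dwi_signals(d.reshape(1, 1, 1, 3, 3), grads, s0=123.0)
        np.testing.assert_allclose(dwi.data, 123.0)

    def test_rank_deficient_scheme_rejected(self):
        bvals = np.concatenate([np.zeros(3), np.full(5, 1000.0)])
        bvecs = np.vstack([np.zeros((3, 3)), np.tile([1.0, 0, 0], (5, 1))])
        grads = GradientTable(bvals=bvals, bvecs=bvecs)
        with pytest.raises(ValueError, match="insufficient gradient scheme"):
            fit_dti_wlls(np.ones(8), grads)

    def test_volume_fit_matches_per_voxel(self):
        grads = default_gradient_table(5)
        tf = random_tensor_field((2, 2, 2), seed=6)
        dwi = generate_dwi_signals(tf, grads)
        maps = fit_dti_volume(dwi, grads)
        fit = fit_dti_wlls(dwi.data[1, 0, 1], grads)
        assert maps["fa"].data[1, 0, 1] == pytest.approx(fit.fa, abs=1e-12)
        assert maps["md"].data[1, 0, 1] == pytest.approx(fit.md, abs=1e-15)


# ---------------------------------------------------------------------------
# motion

def test_motion_screen_policies():
    assert motion_screen(np.zeros(100), 2.0).passed
    res = motion_screen(np.array([0.1, 5.0, 0.2]), 2.0)
    assert not res.passed and res.offending_frames == [1]
    assert motion_screen(np.array([4.0]), 2.0).passed  # boundary passes
    with pytest.raises(ValueError, match="finite"):
        motion_screen(np.array([np.nan]), 2.0)
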