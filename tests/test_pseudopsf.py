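"""Pseudo-PSF pre-processing: specimen cancellation, oracle agreement, cropping."""

import numpy as np
import pytest
from numpy.fft import fft2, fftshift, ifft2, ifftshift

from mlao.datagen import SpecimenSpec, generate_specimen
from mlao.imaging import ModalityConfig, acquire_biased, effective_psf, psf_from_phase
from mlao.pseudopsf import (
    CROP_SIZE,
    compute_pseudo_psf,
    crop_center,
    in_crop_fraction,
    normalize_stack,
    pseudo_psf_pair,
)
from mlao.zernike import ZernikeCoefficients, evaluate_wavefront

BASE = ZernikeCoefficients({5: 0.8, 7: -0.5})
BIAS_P = ZernikeCoefficients({5: 1.0})
BIAS_M = ZernikeCoefficients({5: -1.0})


def _biased_pair(grid, obj, base, cfg):
    ip = acquire_biased(obj, base, BIAS_P, cfg, grid)
    im = acquire_biased(obj, base, BIAS_M, cfg, grid)
    return ip, im


def _norm_corr(a, b):
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def test_identical_inputs_give_center_delta():
    img = np.random.default_rng(0).random((64, 64))
    p = compute_pseudo_psf(img, img, eps=1e-6)
    assert p[32, 32] == pytest.approx(1.0, abs=5e-3)
    off = p.copy()
    off[32, 32] = 0.0
    assert np.abs(off).max() < 5e-3


def test_matches_direct_psf_ratio_oracle(grid, noiseless_2p):
    """On noiseless frames the image-spectral ratio must reduce to the PSF ratio."""
    obj = generate_specimen(SpecimenSpec("texture", seed=3), (grid.n_fft, grid.n_fft))
    ip, im = _biased_pair(grid, obj, BASE, noiseless_2p)
    eps = 1e-5

    def eff(bias):
        return effective_psf(psf_from_phase(evaluate_wavefront(BASE + bias, grid), grid), noiseless_2p)

    # oracle: regularized ratio computed directly from the two effective PSFs
    f1 = fft2(ifftshift(eff(BIAS_P)))
    f2 = fft2(ifftshift(eff(BIAS_M)))
    p2 = np.abs(f2) ** 2
    oracle = fftshift(ifft2(f1 * np.conj(f2) / (p2 + eps * p2.max()))).real

    ours = compute_pseudo_psf(ip, im, eps=eps)
    c_ours, c_oracle = crop_center(ours), crop_center(oracle)
    assert _norm_corr(c_ours, c_oracle) > 0.99
    assert np.abs(c_ours - c_oracle).max() < 0.05 * np.abs(c_oracle).max()


def test_oracle_deviation_shrinks_with_eps(grid, noiseless_2p):
    obj = generate_specimen(SpecimenSpec("texture", seed=5), (grid.n_fft, grid.n_fft))
    ip, im = _biased_pair(grid, obj, BASE, noiseless_2p)
    ref = crop_center(compute_pseudo_psf(ip, im, eps=1e-8))
    devs = [
        np.abs(crop_center(compute_pseudo_psf(ip, im, eps=e)) - ref).max() for e in (1e-2, 1e-4, 1e-6)
    ]
    assert devs[0] > devs[1] > devs[2]


def test_specimen_independence_across_bead_fields(grid, noiseless_2p):
    """Headline property: the pseudo-PSF barely depends on the specimen."""
    crops = []
    for seed in range(10):
        obj = generate_specimen(SpecimenSpec("beads", seed=seed), (grid.n_fft, grid.n_fft))
        ip, im = _biased_pair(grid, obj, BASE, noiseless_2p)
        crops.append(crop_center(compute_pseudo_psf(ip, im)))
    corr = np.corrcoef(np.stack([c.ravel() for c in crops]))
    iu = np.triu_indices(len(crops), 1)
    assert corr[iu].min() > 0.95


def test_aberration_sensitivity_beats_specimen_variation(grid, noiseless_2p):
    same_ab = []
    for seed in range(5):
        obj = generate_specimen(SpecimenSpec("beads", seed=seed), (grid.n_fft, grid.n_fft))
        ip, im = _biased_pair(grid, obj, BASE, noiseless_2p)
        same_ab.append(crop_center(compute_pseudo_psf(ip, im)))
    other = BASE + ZernikeCoefficients({6: 0.7})  # >= 0.5 rad RMS away
    obj = generate_specimen(SpecimenSpec("beads", seed=0), (grid.n_fft, grid.n_fft))
    ip, im = _biased_pair(grid, obj, other, noiseless_2p)
    p_other = crop_center(compute_pseudo_psf(ip, im))
    same_corr = min(
        _norm_corr(a, b) for i, a in enumerate(same_ab) for b in same_ab[i + 1 :]
    )
    cross_corr = max(_norm_corr(a, p_other) for a in same_ab)
    assert cross_corr < same_corr


class TestCrop:
    def test_center_delta_maps_to_16_16(self):
        p = np.zeros((256, 256))
        p[128, 128] = 1.0
        c = crop_center(p)
        assert c.shape == (32, 32)
        assert c[16, 16] == 1.0 and c.sum() == 1.0

    def test_idempotent(self):
        p = np.random.default_rng(1).random((64, 64))
        once = crop_center(p)
        assert np.array_equal(crop_center(once), once)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            crop_center(np.zeros((16, 16)))

    def test_in_crop_fraction_reports_discarded_energy(self):
        p = np.zeros((128, 128))
        p[64, 64] = 3.0  # inside the crop
        p[0, 0] = 1.0  # outside
        assert in_crop_fraction(p) == pytest.approx(0.75)


class TestPair:
    def test_identical_images_give_identical_center_deltas(self):
        img = np.random.default_rng(2).random((64, 64))
        c0, c1 = pseudo_psf_pair(img, img)
        assert np.allclose(c0, c1, atol=1e-10)
        assert c0[16, 16] == pytest.approx(1.0, abs=0.05)

    def test_swapping_inputs_swaps_outputs(self, grid, bead_field, noiseless_2p):
        ip, im = _biased_pair(grid, bead_field, BASE, noiseless_2p)
        c0, c1 = pseudo_psf_pair(ip, im)
        s0, s1 = pseudo_psf_pair(im, ip)
        assert np.allclose(c0, s1) and np.allclose(c1, s0)

    def test_channels_differ_under_base_aberration(self, grid, bead_field, noiseless_2p):
        """Both channels carry sign information: they are not mirror copies."""
        ip, im = _biased_pair(grid, bead_field, BASE, noiseless_2p)
        c0, c1 = pseudo_psf_pair(ip, im)
        assert _norm_corr(c0, c1) < 0.99
        assert _norm_corr(c0, c1[::-1, ::-1]) < 0.99


@pytest.mark.parametrize("eps", [0.0, -1.0])
def test_nonpositive_eps_rejected(eps):
    img = np.ones((64, 64))
    with pytest.raises(ValueError):
        compute_pseudo_psf(img, img, eps=eps)


def test_blank_reference_frame_yields_zero_map():
    # a structureless frame has an all-zero (mean-subtracted) spectrum;
    # the ratio is undefined and the pseudo-PSF degrades to zeros, not NaNs
    blank = np.full((64, 64), 3.0)
    textured = np.random.default_rng(0).random((64, 64))
    out = compute_pseudo_psf(textured, blank)
    assert np.all(out == 0)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        compute_pseudo_psf(np.ones((64, 64)), np.ones((32, 32)))


def test_normalize_stack_scales_each_channel_to_unit_peak():
    stack = np.stack([np.full((32, 32), 4.0), np.full((32, 32), -0.5)])
    out = normalize_stack(stack)
    assert np.abs(out).max(axis=(1, 2)) == pytest.approx([1.0, 1.0])
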