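"""Co-occurrence matrices and features against brute-force oracles."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from texcomplex import glcm
from texcomplex.colorspaces import ChannelImage

_OFFSETS = {
    0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1),
    180: (0, -1), 225: (1, -1), 270: (1, 0), 315: (1, 1),
}


def _brute_force_com(indexed, d, theta, levels):
    """Exhaustive ordered-pair enumeration."""
    dr, dc = (o * d for o in _OFFSETS[theta])
    H, W = indexed.shape
    counts = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                counts[indexed[r, c], indexed[r2, c2]] += 1
    return counts / counts.sum()


def _brute_force_features(P):
    """Independent double-loop evaluation of all five features."""
    L = P.shape[0]
    enrg = cont = entp = homg = 0.0
    mi = mj = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            enrg += p * p
            cont += (i - j) ** 2 * p
            homg += p / (1 + (i - j) ** 2)
            if p > 0:
                entp -= p * np.log2(p)
            mi += i * p
            mj += j * p
    si = np.sqrt(sum((i - mi) ** 2 * P[i, :].sum() for i in range(L)))
    sj = np.sqrt(sum((j - mj) ** 2 * P[:, j].sum() for j in range(L)))
    corr = float("nan")
    if si * sj > 0:
        corr = sum(
            (i - mi) * (j - mj) * P[i, j] for i in range(L) for j in range(L)
        ) / (si * sj)
    return enrg, cont, corr, entp, homg


def test_quantize_bands_and_idempotence():
    ramp = ChannelImage(np.tile(np.linspace(0, 1, 16), (4, 1)), "Int", "intensity")
    q = glcm.quantize(ramp, 4)
    assert np.array_equal(np.unique(q), [0, 1, 2, 3])
    assert all(len(set(q[:, j])) == 1 for j in range(16))  # bands are columns
    const = ChannelImage(np.full((4, 4), 0.9), "Int", "intensity")
    assert len(np.unique(glcm.quantize(const, 8))) == 1
    # idempotence: re-quantizing bin centers reproduces the indices
    centers = (q + 0.5) / 4
    q2 = glcm.quantize(ChannelImage(centers, "Int", "intensity"), 4)
    assert np.array_equal(q, q2)
    with pytest.raises(ValueError):
        glcm.quantize(ramp, 1)


def test_com_constant_and_checkerboard():
    const = np.zeros((6, 6), dtype=int) + 3
    C = glcm.compute_com(const, 1, 45, 8)
    assert C.P[3, 3] == 1.0 and C.P.sum() == 1.0
    cb = (np.indices((8, 8)).sum(axis=0) % 2).astype(int)
    C = glcm.compute_com(cb, 1, 0, 2)
    assert C.P[0, 1] == pytest.approx(0.5) and C.P[1, 0] == pytest.approx(0.5)
    assert C.P[0, 0] == 0.0 and C.P[1, 1] == 0.0


@pytest.mark.parametrize("theta", list(_OFFSETS))
@pytest.mark.parametrize("d", [1, 2])
def test_com_matches_pair_enumeration_oracle(rng, d, theta):
    indexed = rng.integers(0, 4, size=(6, 6))
    C = glcm.compute_com(indexed, d, theta, 4)
    assert np.allclose(C.P, _brute_force_com(indexed, d, theta, 4), atol=1e-12)


def test_axial_com_cross_checked_against_skimage(rng):
    indexed = rng.integers(0, 8, size=(10, 10)).astype(np.uint8)
    mine = glcm.compute_com(indexed, 1, 0, 8).P
    sk = graycomatrix(indexed, [1], [0], levels=8, normed=True)[:, :, 0, 0]
    assert np.allclose(mine, sk, atol=1e-12)


def test_feature_formulas_match_double_loop_oracle(rng):
    indexed = rng.integers(0, 5, size=(8, 8))
    C = glcm.compute_com(indexed, 1, 45, 5)
    enrg, cont, corr, entp, homg = _brute_force_features(C.P)
    f = glcm.com_features(C)
    assert f.enrg_com == pytest.approx(enrg, abs=1e-12)
    assert f.cont_com == pytest.approx(cont, abs=1e-12)
    assert f.corr_com == pytest.approx(corr, abs=1e-12)
    assert f.entp_com == pytest.approx(entp, abs=1e-12)
    assert f.homg_com == pytest.approx(homg, abs=1e-12)


def test_constant_image_degenerate_features():
    C = glcm.compute_com(np.full((6, 6), 2, dtype=int), 1, 0, 4)
    f = glcm.com_features(C)
    assert (f.enrg_com, f.cont_com, f.entp_com, f.homg_com) == (1.0, 0.0, 0.0, 1.0)
    assert np.isnan(f.corr_com)


def test_checkerboard_feature_values():
    cb = (np.indices((8, 8)).sum(axis=0) % 2).astype(int)
    f = glcm.com_features(glcm.compute_com(cb, 1, 0, 2))
    assert f.cont_com == pytest.approx(1.0)
    assert f.enrg_com == pytest.approx(0.5)
    assert f.entp_com == pytest.approx(1.0)
    assert f.homg_com == pytest.approx(0.5)
    assert f.corr_com == pytest.approx(-1.0)


def test_rotation_average_equals_mean_of_per_angle_features(rng):
    ch = ChannelImage(rng.uniform(size=(12, 12)), "Int", "intensity")
    rif = glcm.rotation_invariant_com_features(ch, d=2, levels=8)
    indexed = glcm.quantize(ch, 8)
    per = [glcm.com_features(glcm.compute_com(indexed, 2, t, 8)) for t in glcm.ANGLES_8]
    for k in glcm.FEATURE_NAMES:
        assert getattr(rif, k) == pytest.approx(np.mean([getattr(f, k) for f in per]), abs=1e-12)


def test_rotation_invariant_features_unchanged_by_quarter_turn(rng):
    ch = ChannelImage(rng.uniform(size=(12, 12)), "Int", "intensity")
    rot = ChannelImage(np.rot90(ch.values), "Int", "intensity")
    a = glcm.rotation_invariant_com_features(ch, d=2, levels=8)
    b = glcm.rotation_invariant_com_features(rot, d=2, levels=8)
    for k in glcm.FEATURE_NAMES:
        assert getattr(a, k) == pytest.approx(getattr(b, k), abs=1e-12)


def test_opposite_angles_transpose_so_half_sweep_suffices(rng):
    """Features at theta and theta+180 agree (transpose invariance), so the
    8-angle mean equals the 4-angle mean."""
    indexed = rng.integers(0, 6, size=(9, 9))
    for theta in (0, 45, 90, 135):
        P1 = glcm.compute_com(indexed, 2, theta, 6).P
        P2 = glcm.compute_com(indexed, 2, theta + 180, 6).P
        assert np.allclose(P1, P2.T, atol=1e-15)
    ch = ChannelImage(indexed / 5, "Int", "intensity")
    full = glcm.rotation_invariant_com_features(ch, d=2, levels=6)
    half = glcm.rotation_invariant_com_features(ch, d=2, levels=6, angles=(0, 45, 90, 135))
    for k in glcm.FEATURE_NAMES:
        assert getattr(full, k) == pytest.approx(getattr(half, k), abs=1e-12)


def test_entropy_bound_and_displacement_error():
    rng = np.random.default_rng(3)
    indexed = rng.integers(0, 8, size=(16, 16))
    f = glcm.com_features(glcm.compute_com(indexed, 1, 0, 8))
    assert f.entp_com <= 2 * np.log2(8) + 1e-12
    with pytest.raises(ValueError):
        glcm.compute_com(indexed, 20, 0, 8)


def test_energy_and_entropy_move_oppositely_over_noise_sweep():
    from texcomplex.colorspaces import srgb_to_intensity
    from texcomplex.synthetic import TextureParams, generate_texture

    energies, entropies = [], []
    for a in np.linspace(0.0, 1.0, 5):
        p = TextureParams(size_px=64, noise_amplitude=float(a), seed=9)
        ch = srgb_to_intensity(generate_texture(p))
        f = glcm.rotation_invariant_com_features(ch, d=5, levels=32)
        energies.append(f.enrg_com)
        entropies.append(f.entp_com)
    # opposite monotone directions overall
    assert entropies[-1] > entropies[0]
    assert energies[-1] < energies[0]
    assert np.corrcoef(energies, entropies)[0, 1] < 0
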