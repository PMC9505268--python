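"""Texture generator and simulated observer panels."""

import numpy as np
import pytest

from texcomplex import firstorder, psychophysics as pp, synthetic as syn
from texcomplex.colorspaces import decompose, srgb_to_intensity


def test_determinism_and_shape():
    p = syn.TextureParams(size_px=64, noise_amplitude=0.4, chroma_amplitude=0.3, seed=7)
    a = syn.generate_texture(p)
    b = syn.generate_texture(p)
    assert a.shape == (64, 64, 3)
    assert np.array_equal(a, b)
    assert a.min() >= 0.0 and a.max() <= 1.0


def test_pure_grating_closed_form_sigma():
    # noise-free achromatic texture: sigma(Int) = contrast / (2 sqrt 2)
    for c in (0.2, 0.6, 1.0):
        p = syn.TextureParams(
            size_px=64, grating_period=16, noise_amplitude=0.0,
            contrast_amplitude=c, chroma_amplitude=0.0, seed=1,
        )
        ch = srgb_to_intensity(syn.generate_texture(p))
        assert firstorder.global_std(ch) == pytest.approx(c / (2 * np.sqrt(2)), abs=1e-9)


def test_zero_contrast_yields_constant_image():
    p = syn.TextureParams(size_px=32, contrast_amplitude=0.0, chroma_amplitude=0.0)
    img = syn.generate_texture(p)
    for ch in decompose(img):
        assert np.ptp(ch.values) == pytest.approx(0.0, abs=1e-12), ch.name


def test_chroma_perturbation_leaves_intensity_untouched():
    base = syn.TextureParams(size_px=48, noise_amplitude=0.3, chroma_amplitude=0.0, seed=3)
    withc = syn.TextureParams(size_px=48, noise_amplitude=0.3, chroma_amplitude=0.8, seed=3)
    int_a = srgb_to_intensity(syn.generate_texture(base)).values
    int_b = srgb_to_intensity(syn.generate_texture(withc)).values
    assert np.allclose(int_a, int_b, atol=1e-12)


def test_parameter_validation():
    with pytest.raises(ValueError):
        syn.TextureParams(noise_amplitude=1.5)
    with pytest.raises(ValueError):
        syn.TextureParams(grating_period=1)
    with pytest.raises(ValueError):
        syn.ObserverPanel(sigma_intra=-0.1)


def test_latent_attribute_examples():
    low = syn.latent_attributes(
        syn.TextureParams(noise_amplitude=0, contrast_amplitude=0, chroma_amplitude=0)
    )
    hi = syn.latent_attributes(
        syn.TextureParams(
            size_px=256, grating_period=256 // 2 * 2,  # minimal repetitiveness weight
            noise_amplitude=1, contrast_amplitude=1, chroma_amplitude=1,
        )
    )
    # all amplitudes 1 with regularity 0: positive weights only
    assert hi["complexity"] == pytest.approx(0.50 + 0.34 + 0.41 - 0.14 * hi["repetitiveness"])
    assert hi["complexity"] > low["complexity"]
    assert hi["homogeneity"] == -hi["complexity"]
    # monotone in noise amplitude
    cs = [
        syn.latent_attributes(syn.TextureParams(noise_amplitude=a))["complexity"]
        for a in np.linspace(0, 1, 5)
    ]
    assert all(np.diff(cs) > 0)


def test_noise_free_panel_reproduces_latent_ordering(rng):
    scores = rng.uniform(size=15)
    panel = syn.ObserverPanel(n_observers=4, sigma_intra=0.0, sigma_inter=0.0, seed=2)
    rm = syn.simulate_rankings(scores, panel, replicates=2)
    expected = np.argsort(np.argsort(scores)) + 1
    assert np.all(rm.ranks == expected)
    assert pp.intra_observer_stress(rm).intra == 0.0
    assert pp.inter_observer_stress(rm).inter == 0.0
    v = pp.vrs(rm)
    assert np.array_equal(np.argsort(v.raw), np.argsort(scores))


def test_rankings_equivariant_under_sample_permutation(rng):
    scores = rng.uniform(size=12)
    panel = syn.ObserverPanel(n_observers=3, sigma_intra=0.0, sigma_inter=0.0, seed=5)
    rm = syn.simulate_rankings(scores, panel)
    perm = rng.permutation(12)
    rm_p = syn.simulate_rankings(scores[perm], panel)
    assert np.array_equal(rm_p.ranks, rm.ranks[:, perm])


def test_intra_below_inter_stress_over_many_panels(rng):
    scores = rng.uniform(size=23)
    intra, inter = [], []
    for s in range(50):
        panel = syn.ObserverPanel(n_observers=6, sigma_intra=0.1, sigma_inter=0.3, seed=s)
        rm = syn.simulate_rankings(scores, panel, replicates=2)
        intra.append(pp.intra_observer_stress(rm).intra)
        inter.append(pp.inter_observer_stress(rm).inter)
    assert np.mean(intra) < np.mean(inter)


def test_sigma_and_com_entropy_monotone_with_randomness_sweep():
    """Seed-averaged sweep means of luminance spread and CoM entropy both
    rise monotonically with the randomness driver."""
    from texcomplex import glcm

    sweep = np.linspace(0.0, 1.0, 10)
    sig_means, ent_means = [], []
    for a in sweep:
        sig, ent = [], []
        for seed in range(4):
            p = syn.TextureParams(size_px=96, noise_amplitude=float(a), seed=seed)
            ch = srgb_to_intensity(syn.generate_texture(p))
            sig.append(firstorder.global_std(ch))
            ent.append(glcm.rotation_invariant_com_features(ch, d=10, levels=64).entp_com)
        sig_means.append(np.mean(sig))
        ent_means.append(np.mean(ent))
    assert all(np.diff(sig_means) > 0)
    assert all(np.diff(ent_means) > 0)


def test_attribute_table_and_sampler(rng):
    params = syn.sample_params(10, seed=3, size_px=64)
    tab = syn.attribute_table(params)
    assert list(tab.columns) == list(syn.ATTRIBUTE_NAMES) + ["complexity", "homogeneity"]
    assert len(tab) == 10
    assert tab[list(syn.ATTRIBUTE_NAMES)].to_numpy().min() >= 0.0
    # complexity column equals the weighted sum of the attribute columns
    w = np.array(list(syn.COMPLEXITY_WEIGHTS.values()))
    assert np.allclose(tab["complexity"], tab[list(syn.ATTRIBUTE_NAMES)] @ w, atol=1e-12)


def test_end_to_end_weight_recovery_through_rank_scores():
    """The attribute-model weights are recovered from simulated rank scores:
    60 textures, 10 observers, two replicate sessions, perceptual noise 0.2."""
    import pandas as pd

    from texcomplex import statmodels

    cols = list(syn.ATTRIBUTE_NAMES)
    rng = np.random.default_rng(0)
    tab = syn.attribute_table(syn.sample_params(60, seed=100, size_px=64))
    vrs_cols = {}
    for c in cols + ["complexity"]:
        panel = syn.ObserverPanel(sigma_intra=0.2, sigma_inter=0.0, seed=int(rng.integers(2**31)))
        rm = syn.simulate_rankings(tab[c].to_numpy(), panel, replicates=2)
        vrs_cols[c] = pp.vrs(rm).rescaled
    V = pd.DataFrame(vrs_cols)
    res = statmodels.fit_vtc(V["complexity"].to_numpy(), V[cols].to_numpy(), labels=cols)
    truth = np.array(list(syn.COMPLEXITY_WEIGHTS.values()))
    assert np.all(np.sign(res.params) == np.sign(truth))
    assert np.max(np.abs(res.params - truth)) < 0.08
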